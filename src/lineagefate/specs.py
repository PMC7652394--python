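"""Declarative model specifications.

Two model families are analysed:

* **MN family** ("model 1"): the per-cycle micronucleus indicator is
  Bernoulli with inverse-logit link on a linear predictor in the
  condition dummies, optionally with a per-lineage random intercept
  ("lineage individuality") that is normal or Student-t distributed.
* **Duration family** ("model 2"): the interphase duration is log-normal
  (or, as robustness alternatives, exponential / gamma with the same
  linear predictor); the log-median is linear in the MN indicator
  (coefficient ``micro``) and the condition dummies, which act as
  confounders; the scale parameter differs between experimental
  conditions.

The canonical grids are each {full predictor, minimal predictor} x
{no lineage effect, normal, Student-t}; exact numbering within the grid
is a convention of this package (each analysis output names the spec it
used).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "ModelSpec",
    "canonical_mn_models",
    "canonical_duration_models",
    "get_spec",
]

_ALL_TERMS = ("micro", "scf", "rnf", "stg", "sis2-3")
_CONFOUNDERS = ("scf", "rnf", "stg", "sis2-3")


@dataclass(frozen=True)
class ModelSpec:
    """One statistical model: response, likelihood, predictors, hierarchy."""

    name: str
    response: str  # "MN" | "interphase_duration"
    likelihood: str  # "bernoulli_logit" | "lognormal" | "exponential" | "gamma"
    terms: tuple[str, ...]
    lineage_effect: str = "none"  # "none" | "normal" | "student_t"
    sigma_grouping: str = "none"  # "none" | "shared" | "by_condition"
    student_t_df: float = 4.0

    def __post_init__(self) -> None:
        if self.response not in {"MN", "interphase_duration"}:
            raise ValueError(f"unknown response {self.response!r}")
        if self.likelihood not in {"bernoulli_logit", "lognormal", "exponential", "gamma"}:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.lineage_effect not in {"none", "normal", "student_t"}:
            raise ValueError(f"unknown lineage_effect {self.lineage_effect!r}")
        if self.sigma_grouping not in {"none", "shared", "by_condition"}:
            raise ValueError(f"unknown sigma_grouping {self.sigma_grouping!r}")
        unknown = set(self.terms) - set(_ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown term(s) {sorted(unknown)}")
        if self.response == "MN" and "micro" in self.terms:
            raise ValueError("micro (MN coefficient) only applies to duration models")
        if self.likelihood == "bernoulli_logit" and self.sigma_grouping != "none":
            raise ValueError("bernoulli_logit has no scale parameter")

    @property
    def hierarchical(self) -> bool:
        return self.lineage_effect != "none"

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "response": self.response,
                "likelihood": self.likelihood,
                "terms": list(self.terms),
                "lineage_effect": self.lineage_effect,
                "sigma_grouping": self.sigma_grouping,
                "student_t_df": self.student_t_df,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["terms"] = tuple(d["terms"])
        return cls(**d)


def _registry(specs: Iterable[ModelSpec]) -> dict[str, ModelSpec]:
    out: dict[str, ModelSpec] = {}
    for s in specs:
        if s.name in out:
            raise ValueError(f"duplicate spec name {s.name!r}")
        out[s.name] = s
    return out


def canonical_mn_models() -> dict[str, ModelSpec]:
    """The six-member MN (model 1) grid.

    ``1_2`` is the full predictor without hierarchy, ``1_4`` the scf-only
    predictor without hierarchy (the study's two most predictive
    structures); odd numbers carry the normal lineage effect, 5/6 the
    Student-t variants.
    """

    def mn(name: str, terms: tuple[str, ...], effect: str) -> ModelSpec:
        return ModelSpec(
            name=name, response="MN", likelihood="bernoulli_logit", terms=terms,
            lineage_effect=effect,
        )

    return _registry(
        [
            mn("1_1", _CONFOUNDERS, "normal"),
            mn("1_2", _CONFOUNDERS, "none"),
            mn("1_3", ("scf",), "normal"),
            mn("1_4", ("scf",), "none"),
            mn("1_5", _CONFOUNDERS, "student_t"),
            mn("1_6", ("scf",), "student_t"),
        ]
    )


def canonical_duration_models() -> dict[str, ModelSpec]:
    """The eight-member interphase-duration (model 2) registry.

    Six log-normal structures mirror the MN grid with ``micro`` always
    present; ``2_2`` (micro + all confounders, no hierarchy, condition-
    specific scale) is the study's best performer, and ``2_2_exp`` /
    ``2_2_gamma`` swap the likelihood while keeping its linear predictor.
    """

    def dur(name: str, terms: tuple[str, ...], effect: str, lik: str = "lognormal") -> ModelSpec:
        # exponential fixes its spread through the mean, so it carries no
        # separate scale; lognormal sigma and gamma shape vary by condition
        grouping = "none" if lik == "exponential" else "by_condition"
        return ModelSpec(
            name=name, response="interphase_duration", likelihood=lik,
            terms=("micro",) + terms, lineage_effect=effect,
            sigma_grouping=grouping,
        )

    return _registry(
        [
            dur("2_1", _CONFOUNDERS, "normal"),
            dur("2_2", _CONFOUNDERS, "none"),
            dur("2_3", (), "normal"),
            dur("2_4", (), "none"),
            dur("2_5", _CONFOUNDERS, "student_t"),
            dur("2_6", (), "student_t"),
            dur("2_2_exp", _CONFOUNDERS, "none", lik="exponential"),
            dur("2_2_gamma", _CONFOUNDERS, "none", lik="gamma"),
        ]
    )


def get_spec(name: str) -> ModelSpec:
    """Look a spec up by name across both canonical registries."""
    for reg in (canonical_mn_models(), canonical_duration_models()):
        if name in reg:
            return reg[name]
    raise KeyError(f"no canonical model named {name!r}")
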
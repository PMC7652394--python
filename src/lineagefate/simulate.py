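"""Branching-process generator of synthetic live-cell lineage datasets.

The generator inverts the regression models: within each cell cycle a
micronucleus (MN) is drawn first from a Bernoulli with logit-linear
probability in the condition dummies, then the interphase duration from a
log-normal whose log-median depends linearly on MN status and the same
dummies, then a mitotic duration; divisions spawn daughters until the end
of the imaging window.  Observation artefacts of the study design are
emulated: frame quantization, censoring at movie end, reporter fading in
newly rearranged lineages, and sporadic death / sister-fusion /
multi-nucleation / tripolar / furrow-regression events.

The defaults encode the study conditions: six conditions (cell line
{CTRL48, SIS2-3} x treatment {mCit, sgF11} x stage {1+x, N+x}, mock
treatment only in N+x), 51 founders per condition, a 66-h movie at 10-min
frames, MN effect scf = 2.44 on the logit scale over a baseline MN
probability of 0.0102 per cycle, and MN effect micro = 0.820 on the
log-duration scale over a 17-h baseline median interphase.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import CellRecord, TidyDataset

__all__ = ["GenParams", "CONDITIONS", "default_params", "simulate_dataset", "inv_logit", "logit"]

#: The six experimental conditions (cell_line, treatment, stage); mock
#: (mCit) cells are fluorescent from the start of the movie, hence N+x only.
CONDITIONS = (
    ("CTRL48", "mCit", "N+x"),
    ("CTRL48", "sgF11", "1+x"),
    ("CTRL48", "sgF11", "N+x"),
    ("SIS2-3", "mCit", "N+x"),
    ("SIS2-3", "sgF11", "1+x"),
    ("SIS2-3", "sgF11", "N+x"),
)


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


@dataclass
class GenParams:
    """Generator parameters; defaults are the documented study conditions."""

    n_lineages: int = 51  # founders per condition
    movie_length: float = 66.0  # hours
    frame_interval_min: float = 10.0  # minutes per frame (6-12 in the study)
    onset_window: float = 22.0  # hours; 1+x founders turn on uniformly here

    # MN model (logit scale)
    mn_b: float = float(logit(0.0102))
    mn_scf: float = 2.44
    mn_rnf: float = 0.0
    mn_stg: float = 0.0
    mn_sis: float = 0.0
    mn_lineage_sd: float = 0.0

    # duration model (log-hours scale)
    dur_b: float = math.log(17.0)
    dur_micro: float = 0.820
    dur_scf: float = 0.0
    dur_rnf: float = 0.0
    dur_stg: float = 0.0
    dur_sis: float = 0.0
    dur_lineage_sd: float = 0.0
    sigma: tuple[float, ...] = (0.25,) * 6  # log-scale sd per condition (sorted order)

    mitosis_log_median: float = math.log(0.75)  # hours
    mitosis_log_sd: float = 0.3

    # per-cycle event probabilities (plumbing defaults, small)
    p_death: float = 0.01
    p_fusion: float = 0.005
    p_bi_multi: float = 0.005
    p_tripolar: float = 0.002
    p_regression: float = 0.002

    fading_enabled: bool = True
    fading_prob: float = 0.5  # chance one daughter of the first division fades
    seed: int | None = None

    def validate(self) -> None:
        for name in ("p_death", "p_fusion", "p_bi_multi", "p_tripolar", "p_regression", "fading_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma entries must be > 0")
        if self.movie_length <= 0:
            raise ValueError("movie_length must be > 0")
        if not 6.0 <= self.frame_interval_min <= 12.0:
            raise ValueError("frame_interval_min outside the study's 6-12 min range")

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["sigma"] = list(d["sigma"])
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GenParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["sigma"] = tuple(d["sigma"])
        return cls(**d)


def default_params() -> GenParams:
    """The documented defaults (see module docstring)."""
    return GenParams()


def _quantize(x: float, frame: float, minimum: float = 0.0) -> float:
    q = round(x / frame) * frame
    return max(q, minimum)


def simulate_dataset(params: GenParams | None = None, seed: int | None = None) -> TidyDataset:
    """Simulate one tidy dataset.  Same ``(params, seed)`` gives
    byte-identical output through :func:`lineagefate.data.write_tidy`."""
    params = params or default_params()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    frame = params.frame_interval_min / 60.0
    end = params.movie_length
    records: list[CellRecord] = []

    sorted_conditions = sorted(CONDITIONS)
    sigma_of = dict(zip(sorted_conditions, params.sigma))

    for cond in CONDITIONS:
        cell_line, treatment, stage = cond
        scf = float(cell_line == "SIS2-3" and treatment == "sgF11")
        rnf = float(cell_line == "CTRL48" and treatment == "sgF11")
        stg = float(stage == "N+x")
        sis = float(cell_line == "SIS2-3")
        eta_mn_base = (
            params.mn_b
            + params.mn_scf * scf
            + params.mn_rnf * rnf
            + params.mn_stg * stg
            + params.mn_sis * sis
        )
        mu_dur_base = (
            params.dur_b
            + params.dur_scf * scf
            + params.dur_rnf * rnf
            + params.dur_stg * stg
            + params.dur_sis * sis
        )
        sigma_c = sigma_of[cond]
        fades_here = params.fading_enabled and scf == 1.0 and stage == "1+x"
        tag = f"{cell_line}.{treatment}.{stage.replace('+', '')}"

        for j in range(params.n_lineages):
            lineage_id = f"{tag}.{j:03d}"
            lin_mn = rng.normal(0.0, params.mn_lineage_sd) if params.mn_lineage_sd > 0 else 0.0
            lin_dur = rng.normal(0.0, params.dur_lineage_sd) if params.dur_lineage_sd > 0 else 0.0
            onset = _quantize(rng.uniform(0.0, params.onset_window), frame) if stage == "1+x" else 0.0

            first_division_done = False
            # FIFO queue of (cell_id, parent_id, t_birth, fate, fused_with)
            # fate: "normal" | "fade" | "fused_end" | "fused_tripolar"
            queue: list[tuple[str, str | None, float, str, str | None]] = [
                ("a", None, onset, "normal", None)
            ]
            while queue:
                cell_id, parent_id, t_birth, fate, fused_with = queue.pop(0)
                base = dict(
                    lineage_id=lineage_id,
                    cell_id=cell_id,
                    parent_id=parent_id,
                    cell_line=cell_line,
                    treatment=treatment,
                    stage=stage,
                    t_birth=round(t_birth, 9),
                    fused_with=fused_with,
                )
                if fate == "fade":
                    records.append(CellRecord(**base, fading=True))
                    continue
                if fate == "fused_end":
                    records.append(CellRecord(**base))
                    continue

                mn = bool(rng.random() < inv_logit(eta_mn_base + lin_mn))
                bi_multi = bool(rng.random() < params.p_bi_multi)
                mu = mu_dur_base + params.dur_micro * mn + lin_dur
                interphase = _quantize(math.exp(rng.normal(mu, sigma_c)), frame, minimum=frame)
                t_nebd = t_birth + interphase

                if rng.random() < params.p_death:
                    # dies before reaching mitosis; branch ends
                    records.append(
                        CellRecord(**base, micronuclei=mn, bi_multi_nuclei=bi_multi, death=True)
                    )
                    continue
                if t_nebd > end:
                    records.append(
                        CellRecord(
                            **base, micronuclei=mn, bi_multi_nuclei=bi_multi, censored=True
                        )
                    )
                    continue

                mitotic = _quantize(
                    math.exp(rng.normal(params.mitosis_log_median, params.mitosis_log_sd)),
                    frame,
                    minimum=frame,
                )
                t_division = t_nebd + mitotic
                if t_division > end:
                    records.append(
                        CellRecord(
                            **base,
                            micronuclei=mn,
                            bi_multi_nuclei=bi_multi,
                            t_nebd=round(t_nebd, 9),
                            interphase_duration=round(interphase, 9),
                            censored=True,
                        )
                    )
                    continue

                tripolar = fate == "fused_tripolar" or (rng.random() < params.p_tripolar)
                regression = (not tripolar) and rng.random() < params.p_regression
                records.append(
                    CellRecord(
                        **base,
                        micronuclei=mn,
                        bi_multi_nuclei=bi_multi,
                        t_nebd=round(t_nebd, 9),
                        t_division=round(t_division, 9),
                        interphase_duration=round(interphase, 9),
                        mitotic_duration=round(mitotic, 9),
                        tripolar=tripolar,
                        regression=regression,
                    )
                )

                if regression:
                    # cytokinesis failure: a single binucleate continuation
                    queue.append((cell_id + "a", cell_id, t_division, "normal", None))
                    first_division_done = True
                    continue
                n_kids = 3 if tripolar else 2
                kid_ids = [cell_id + suffix for suffix in "abc"[:n_kids]]
                fates = ["normal"] * n_kids
                kid_fused: list[str | None] = [None] * n_kids
                if (
                    not first_division_done
                    and fades_here
                    and n_kids == 2
                    and rng.random() < params.fading_prob
                ):
                    # the reporter segregates: one daughter of the first
                    # division loses mCitrine and leaves the observed set
                    fates[int(rng.integers(0, 2))] = "fade"
                elif n_kids == 2 and rng.random() < params.p_fusion:
                    # sister fusion; the merged cell divides tripolar
                    fates = ["fused_tripolar", "fused_end"]
                    kid_fused = [kid_ids[1], kid_ids[0]]
                first_division_done = True
                for kid, f, fw in zip(kid_ids, fates, kid_fused):
                    queue.append((kid, cell_id, t_division, f, fw))

    return TidyDataset(
        records=records,
        provenance={"generator": "lineagefate.simulate", "seed": seed, "params": json.loads(params.to_json())},
    )
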
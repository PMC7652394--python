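"""Model / Results objects tying the pipeline together.

Usage follows the fit-then-inspect idiom of statistical modelling
packages::

    spec = get_spec("1_4")
    model = LineageFateModel.from_dataset(dataset, spec)
    res = model.fit(seed=0)
    res.summary()            # medians, credible intervals, R-hat, ESS
    res.waic()               # generalization-loss-scale WAIC
    res.predict_mn_prob({"scf": 1})

A :class:`LineageFateModel` is one model spec bound to one design matrix;
``fit`` runs the reference sampler and returns a
:class:`LineageFateResults` carrying the posterior draws, the pointwise
log-likelihood matrix, diagnostics, and the posterior-predictive methods.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import prediction as _pred
from .data import TidyDataset
from .design import ModelData, condition_covariates, design_matrix
from .diagnostics import summarize
from .likelihoods import ParameterSet, pointwise_loglik
from .sampler import PosteriorDraws, Priors, SamplerConfig, sample_posterior
from .specs import ModelSpec, get_spec
from .waic import WaicResult, waic

__all__ = ["LineageFateModel", "LineageFateResults"]


class LineageFateModel:
    """One model spec bound to one dataset's design matrix."""

    def __init__(self, spec: ModelSpec | str, data: ModelData):
        self.spec = get_spec(spec) if isinstance(spec, str) else spec
        self.data = data

    @classmethod
    def from_dataset(cls, dataset: TidyDataset, spec: ModelSpec | str) -> "LineageFateModel":
        return cls(spec, design_matrix(dataset))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec | str) -> "LineageFateModel":
        return cls(spec, design_matrix(TidyDataset.from_frame(df)))

    def loglik(self, params: ParameterSet) -> np.ndarray:
        """Pointwise log-likelihood at one parameter point."""
        return pointwise_loglik(self.spec, params, self.data)

    def fit(
        self,
        chains: int = 4,
        iterations: int = 2000,
        warmup: int = 1000,
        seed: int | None = None,
        priors: Priors | None = None,
    ) -> "LineageFateResults":
        config = SamplerConfig(
            chains=chains,
            iterations=iterations,
            warmup=warmup,
            seed=seed,
            priors=priors or Priors(),
        )
        draws = sample_posterior(self.spec, self.data, config)
        return LineageFateResults(self, draws)


class LineageFateResults:
    """Posterior draws for one fitted model, with summaries and
    posterior-predictive methods."""

    def __init__(self, model: LineageFateModel, draws: PosteriorDraws):
        self.model = model
        self.spec = model.spec
        self.data = model.data
        self.draws = draws
        self._waic: WaicResult | None = None

    # -- summaries ---------------------------------------------------------

    def summary(self, include_lineage: bool = False) -> pd.DataFrame:
        return summarize(self.draws, include_lineage=include_lineage)

    @property
    def rhat(self) -> dict[str, float]:
        return dict(self.draws.metadata["rhat"])

    @property
    def warnings(self) -> list[str]:
        return list(self.draws.metadata["warnings"])

    def posterior(self, name: str) -> np.ndarray:
        return self.draws.get(name)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.draws.get(name)
        lo = 100 * (1 - level) / 2
        return tuple(np.percentile(x, [lo, 100 - lo]))

    def waic(self) -> WaicResult:
        if self._waic is None:
            self._waic = waic(self.draws.log_lik, model_name=self.spec.name)
        return self._waic

    # -- posterior prediction ---------------------------------------------

    def predict_mn_prob(self, covariates: dict[str, float], seed: int | None = None) -> dict:
        return _pred.predict_mn_prob(self.draws, self.spec, covariates, seed=seed)

    def mn_fold_change(
        self,
        covariates_with: dict[str, float],
        covariates_without: dict[str, float] | None = None,
        seed: int | None = None,
    ) -> dict:
        without = covariates_without if covariates_without is not None else {}
        return _pred.mn_fold_change(self.draws, self.spec, covariates_with, without, seed=seed)

    def predictive_durations(
        self,
        condition: tuple[str, str, str] | int,
        mn_status: int,
        m: int = 10_000,
        seed: int | None = None,
        integrate_posterior: bool = True,
    ) -> np.ndarray:
        """Predictive interphase durations for one experimental condition.

        ``condition`` is a (cell_line, treatment, stage) tuple present in
        the fitted dataset, or directly a condition index.
        """
        if isinstance(condition, int):
            idx = condition
            cond = self.data.conditions[idx]
        else:
            if condition not in self.data.conditions:
                raise KeyError(f"condition {condition} not in fitted data")
            idx = self.data.conditions.index(condition)
            cond = condition
        cov = condition_covariates(*cond)
        return _pred.predictive_duration_samples(
            self.draws,
            self.spec,
            cov,
            mn_status=mn_status,
            condition_index=idx,
            m=m,
            seed=seed,
            integrate_posterior=integrate_posterior,
        )

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist draws and metadata as a columnar text bundle
        (draws.csv + metadata.json; lineage intercepts in lineage.csv)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.draws.flat(), columns=self.draws.names).to_csv(
            d / "draws.csv", index=False
        )
        if self.draws.lineage_draws is not None:
            n_lin = self.draws.lineage_draws.shape[2]
            pd.DataFrame(
                self.draws.lineage_draws.reshape(-1, n_lin),
                columns=[f"lin[{i}]" for i in range(n_lin)],
            ).to_csv(d / "lineage.csv", index=False)
        meta = dict(self.draws.metadata)
        meta["spec_json"] = json.loads(self.spec.to_json())
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))
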
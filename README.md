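# lineagefate

Bayesian fate analysis of live-cell lineage trees: what happens to a cell
and its descendants after a single, defined sister-chromatid fusion (SCF)?

Starting from tidy per-cell-cycle tracking tables (one row per observed
cell cycle, with condition labels, lineage links, event flags and
durations), the package fits hierarchical Bayesian regression models of
micronucleus (MN) formation and interphase duration, selects among model
structures by WAIC, converts posteriors into predictive effect sizes, and
compares matched MN+/MN− sister lineages.  A branching-process simulator
emulates the statistical structure of such datasets so the entire pipeline
is testable without imaging data.

## The models

Per-cycle MN formation is Bernoulli with an inverse-logit link,

```
MN_n ~ Bernoulli(q_n),   logit(q_n) = b + scf·SCF_n + rnf·RNF_n + stg·STG_n + sis·SIS_n + lin_l(n)
```

where the dummies code condition (SCF: fusion induced; RNF: repaired
without fusion; STG: late observation stage; SIS: cell-line effect) and
`lin_i` is an optional per-lineage random intercept.  Interphase duration
is log-normal with condition-specific scale,

```
Int_duration_n ~ LogNormal(mu_n, sigma_c(n)),   mu_n = b + micro·MN_n + (confounders)
```

with exponential and gamma alternatives sharing the same linear predictor.
Models are compared by WAIC on the generalization-loss scale (nat/sample);
a difference is significant when it exceeds one on the AIC scale
(`|delta| x n x 2 > 1`).  `exp(micro)` is the multiplicative effect of an
MN on the median cycle duration; the ratio of averaged posterior MN
probabilities with/without SCF is the headline MN effect.

See `docs/methods.md` for priors, the sampler, and every numerical
convention.

## Worked example

```python
import numpy as np
from lineagefate import (LineageFateModel, default_params, design_matrix,
                         simulate_dataset, rank_models)

dataset = simulate_dataset(default_params(), seed=3)     # ~4,400 cycles
data = design_matrix(dataset)

mn = LineageFateModel("1_4", data).fit(seed=1)           # MN ~ scf
print(mn.summary().round(3)[["median", "q2.5", "q97.5", "rhat"]])
fc = mn.mn_fold_change({"scf": 1}, {})
print(f"fold change: {fc['fold_change']:.2f} "
      f"({fc['average_without']:.4f} -> {fc['average_with']:.3f})")

dur = LineageFateModel("2_2", data).fit(seed=1)          # duration ~ micro + confounders
micro = np.median(dur.posterior("micro"))
print(f"micro median: {micro:.3f}  (exp: {np.exp(micro):.2f}x)")
print(rank_models([mn.waic(), LineageFateModel('1_2', data).fit(seed=1).waic()])
      [["model", "waic_per_sample", "delta_aic_scale_vs_best"]])
```

prints (seeds as above):

```
           median   q2.5  q97.5   rhat
parameter
b          -4.419 -4.806 -4.131  1.040
scf         2.314  1.965  2.749  1.042
fold change: 9.16 (0.0119 -> 0.109)
micro median: 0.774  (exp: 2.17x)
  model  waic_per_sample  delta_aic_scale_vs_best
0   1_4         0.136611                 0.000000
1   1_2         0.137215                 5.069722
```

i.e. on this synthetic dataset the fitted SCF effect raises the per-cycle
MN probability from ~1.2% to ~11% (9.2-fold), an MN multiplies the median
interphase duration by ~2.2, and the parsimonious scf-only model out-
predicts the full-covariate one by 5 AIC-scale units.

The same stages are available from the shell:

```
lineagefate simulate --seed 1 --out data.csv
lineagefate all --input data.csv --seed 1 --out run/     # full pipeline + manifest
lineagefate trees data.csv --out gallery/                # SVG lineage trees
```

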
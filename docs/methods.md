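# Methods

`lineagefate` analyses tidy per-cell-cycle tables from live-cell imaging of
a fluorescent reporter system in which a CRISPR-induced rearrangement marks
cells carrying a single, defined sister-chromatid fusion (SCF).  The
scientific questions are: does a single SCF raise the per-cycle probability
of micronucleus (MN) formation, and does an MN in turn destabilize the cell
cycle?  This note records the models, the generator that emulates the data,
and the numerical and design choices, so that every result the package
prints can be traced to a documented decision.

## Data model

One row is one observed cell cycle of one mCitrine-positive cell.  Six
experimental conditions arise from cell line {CTRL48, SIS2-3} × treatment
{mCit mock, sgF11 CRISPR} × stage {1+x, N+x}; mock-treated cells are
fluorescent from movie start, so mock occurs only at stage N+x.  Condition
dummies code the regression inputs:

* `SCF = 1` for (SIS2-3, sgF11): the cell carries the induced fusion;
* `RNF = 1` for (CTRL48, sgF11): cut-and-repaired, no fusion;
* `STG = 1` for stage N+x; `SIS = 1` for the SIS2-3 line;
* `MN` is the per-cycle micronucleus flag.

An interphase duration exists only when nuclear-envelope breakdown (NEBD)
was observed; cycles truncated by the end of the movie are flagged censored
and carry no duration.  Censored cycles still contribute their MN flag to
the MN model (MN is scored at cycle start).

## Model families

**MN family (model 1).**  `MN_n ~ Bernoulli(q_n)` with
`logit(q_n) = b + scf·SCF_n + rnf·RNF_n + stg·STG_n + sis·SIS_n (+ lin_{l(n)})`.
The optional per-lineage intercept `lin_i` ("lineage individuality",
normal or Student-t with estimated scale, df = 4 by default) captures the
possibility that cells of one tree share unobserved tendencies.  The
canonical grid is {full predictor, scf-only} × {none, normal, Student-t
lineage effect}; `1_2` is full/no-hierarchy, `1_4` scf-only/no-hierarchy.
The exact numbering within the grid is this package's convention; every
output names the spec it used.

**Duration family (model 2).**  `log median` of the interphase duration is
`mu_n = b + micro·MN_n + scf·SCF_n + … (+ lin)`; the likelihood is
log-normal with a condition-specific scale `sigma_c` (six values).  The
condition dummies enter as confounders (they can affect duration only
through or alongside MN, with MN drawn first within a cycle).  `2_2` is
micro + all confounders, no hierarchy.  Robustness alternatives `2_2_exp`
and `2_2_gamma` keep the same linear predictor with exponential and gamma
likelihoods; both are parameterized so that `exp(mu_n)` is the **mean**
(gamma shape `alpha_c` per condition, rate `alpha_c / exp(mu_n)`), which
makes the gamma reduce exactly to the exponential at `alpha_c = 1`.  The
mean parameterization is this package's documented choice; it is isolated
in `likelihoods.py` so an alternative link is a one-line change.

Because `exp` is monotone, a shift `delta` in `mu` multiplies the
log-normal median by `exp(delta)` exactly: the fitted `micro` is read as a
multiplicative effect of MN on the median interphase duration,
`exp(0.820) ≈ 2.27`.

## Priors and sampling

Defaults: coefficients and bias `Normal(0, 10)`; log-normal sigma, gamma
shape and the hierarchical scale `half-Normal(0, 5)`.  All priors are
proper and recorded in every result's metadata.

The reference sampler is an adaptive random-walk Metropolis-within-Gibbs:
scalar parameters take one-at-a-time Gaussian updates whose steps adapt
toward 0.44 acceptance during warmup (Robbins-Monro, `t^-0.6` schedule);
scale-like parameters are sampled on the log scale with the Jacobian folded
into the prior; lineage intercepts are updated as a vectorized block with
independent accept/reject per lineage, valid because likelihood and prior
factorize over lineages given the shared parameters.  Defaults are 4 chains
× 2,000 iterations with 1,000 warmup, sequential chains from independently
spawned RNG streams; a fixed seed reproduces draws bit-for-bit.  The
sampler is a contract — anything producing exchangeable draws plus the
pointwise log-likelihood matrix could replace it.

Convergence is monitored with rank-normalized split R-hat and
Geyer-truncated effective sample size; R-hat > 1.05 attaches a warning to
the result rather than raising, and constant chains report R-hat 1 by
convention.  Summaries are empirical quantiles with linear interpolation
(median, 50% and 95% intervals).

## Model selection

WAIC is reported per sample in nats on the generalization-loss scale:
`lppd_i = log mean_s exp(loglik_si)` (log-sum-exp), penalty
`p_i = Var_s loglik_si` with the (n−1)-denominator estimator (Watanabe's
population form differs by (S−1)/S; the choice is documented and the
deviance-scale value is also emitted for cross-toolchain checks).  Two
models differ significantly when the per-sample gap, converted to the AIC
scale (`|delta| × n × 2`), exceeds one.  Duration-family WAICs are computed
on the observed-duration subset (one shared n within the family), MN-family
WAICs on all records.

## Posterior prediction

MN probabilities are per-draw `inv_logit` transforms; for hierarchical
specs a new lineage's intercept is drawn from its population distribution
per posterior draw.  The headline fold change is the ratio of *averaged*
posterior probabilities (the per-draw ratio distribution is also
returned).  Predictive durations are sampled by pushing posterior draws
through the likelihood (default m = 10,000, seeded); by default the
posterior is integrated over, with a plug-in (posterior-median) mode
available since the study's figure wording is ambiguous between the two.
Quartiles/IQR use linear interpolation; the two-sample Kolmogorov-Smirnov
distance compares predictive samples, with the asymptotic p-value treated
as display-only at predictive sample sizes.

## Sister pairs

Every bipolar division whose two daughter subtrees are discordant for MN
(exactly one side contains an MN cell anywhere in its subtree) yields a
matched pair.  Each side tallies subsequent abnormalities — additional MN,
furrow regression, cell fusion, death, mitotic delay (> 2 h, strict) — and
the number of mitoses; the index MN that defines the positive side is the
matching criterion and is excluded from its own tally.  A side is "more
abnormal" when its tally (plus one point for fewer mitoses) strictly
exceeds the sister's; ties count as "not more" on both rows of the 2×2
table, which is tested with Pearson's chi-square (no continuity correction
by default).  The abnormality-probability estimate is reported under four
estimators (MLE, Jeffreys and Laplace posterior means, Jeffreys posterior
median) since none is canonical.

## Synthetic-data generator

The generator inverts the two regressions as a branching process and
emulates the study's observation artefacts.  Defaults (the documented
study conditions): 51 founders per condition (≈ 305 trees, ≈ 4,400 cycle
records), 66-h movie, 10-min frames (all times quantized to the frame,
durations at least one frame), `scf = 2.44` over a baseline per-cycle MN
probability `inv_logit(b) = 0.0102` (so an SCF cell's MN probability is
0.106), `micro = 0.820` over a baseline median interphase of 17 h
(log-scale sd 0.25 per condition), mitosis log-median `log 0.75 h`
(sd 0.3), `rnf = stg = sis = 0` and lineage-effect sd 0 (the
non-hierarchical, scf-only truth), small sporadic event rates (death 0.01,
fusion 0.005, bi/multi-nucleation 0.005, tripolar 0.002, regression 0.002
per cycle), and reporter fading in newly rearranged (SIS-2-3 sgF11 1+x)
lineages: with probability 0.5 one daughter of the first division loses the
marker and leaves the observed set, mimicking segregation of the tagged
chromosome.  1+x founders switch on at a uniform time in the first 22 h;
N+x founders are tracked from movie start.  Within a cycle the causal
order is MN first, then duration — so MN can lengthen the cycle but not
vice versa.  Baseline duration, sigma, mitosis parameters and the sporadic
rates are one-time package choices where the study prints no value.

What the generator does **not** emulate: mechanistic bridge breakage or
chromothripsis, fluorescence intensities, inter-lineage fusion partners,
left-censoring of mid-cycle N+x founders at movie start, and any
correlation between sporadic events and condition.  Passing recovery tests
therefore show that the inference machinery is correct under the stated
generative assumptions, not that those assumptions hold in real movies.

## Known limitation: movie-end truncation bias

Movie-end censoring interacts with the duration model's design (censored
interphases are excluded from fitting).  Long interphases — which MN cells
have, median ≈ 38.6 h against a 66-h movie — are preferentially truncated,
so the naive log-normal fit underestimates `micro` by ≈ 0.06 at study
scale, comparable to its posterior sd (≈ 0.05).  A controlled experiment
(fitting the same branching-process data with the latent durations of
censored cycles included) recovers `micro` without bias, isolating
truncation as the cause.  Consequently the 95% CI for `micro` covers the
generative 0.820 in roughly 70% of simulation replicates rather than the
nominal 95%, and the empirical median log-duration gap converges to
≈ 0.76, not 0.820.  A censoring-aware (survival) duration likelihood would
remove the bias but is outside this package's scope; the `scf` coefficient
of the MN model is unaffected (MN status is observed even for censored
cycles).

## Problem sizes used in tests

The recovery study fits both families to 20 independent datasets at the
default scale (≈ 4,400 records) with 2 chains × 1,200 iterations (600
warmup); single-fit examples and the acceptance script use the package
defaults of 4 × 2,000.  Monte-Carlo checks of generator rates use 500
founders per condition (≈ 44,000 records).
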
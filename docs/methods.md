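# Methods

## The problem

Sequencing a microbiome specimen captures only an unknown fraction of the
organisms present in a unit volume of the source ecosystem.  That
*sampling fraction* `c_jk` (empirically: library size / microbial load)
varies from sample to sample and is usually confounded with study group —
groups can differ in microbial load while producing similar library
sizes.  A naive comparison of counts between groups therefore mixes true
differences in absolute abundance with differences in sampling fractions,
inflating false positives.  Normalizing by library size alone (total-sum
scaling and relatives) does not remove the confounding because library
size says nothing about microbial load.

## Model

For taxon `i`, group `j`, sample `k`, the log observed count is modeled as

    y_ijk = d_jk + mu_ij + eps_ijk,      E[eps] = 0,

where `d_jk = log c_jk` is a per-sample offset shared by **all** taxa in a
sample and `mu_ij` is the log mean absolute abundance.  Least squares
gives

    d_hat_jk  = ybar_.jk − ybar_.j.      (per-sample taxon mean, centered
                                          within group)
    mu_hat_ij = ybar_ij.                 (per-taxon within-group mean)

`mu_hat_ij` is biased by the group-average offset `dbar_j.`; the
difference of those averages,

    delta = dbar_1. − dbar_2.,

shifts every per-taxon contrast `Delta_i = mu_hat_i1 − mu_hat_i2` by the
same amount.  Because the shift is common across hundreds of taxa it can
be estimated by pooling: `Delta_i` is modeled as a three-component
Gaussian mixture — null taxa centered at `delta`, down-shifted taxa at
`delta + l1` (`l1 < 0`), up-shifted at `delta + l2` (`l2 > 0`) — with
per-taxon null variances `nu2_i0 = sigma2_i1 + sigma2_i2` plugged in from
the residual variance estimator `sigma2_ij = RSS_ij / n_j^2` (which
estimates `Var(mu_hat_ij)` directly; no degrees-of-freedom correction).
Non-null component variances are `nu2_i0 + kappa_r` with `kappa_r >= 0`.

A generalized E–M algorithm maximizes the mixture likelihood:

* E-step: standard responsibilities with proper normal densities
  (standard deviation `sqrt(nu2_ir)`).
* M-step: mixing proportions in closed form; `delta` as the
  responsibility- and inverse-variance-weighted mean of `Delta_i − l_r`;
  `l1`, `l2` as weighted component means clamped to their sign
  constraints; `kappa_1`, `kappa_2` by bounded one-dimensional numeric
  maximization (no closed form exists because `nu2_i0` varies by taxon),
  keeping the incumbent value when the numeric optimum does not improve
  the objective.

Every step ascends the EM lower bound, so the observed-data
log-likelihood is non-decreasing; the test suite asserts this on every
fixture.  Initialization: `delta` at the median of `Delta` (robust to
non-null contamination), the lower/upper 10% tails seeding the down/up
components, `kappa = 0`.  Convergence: absolute log-likelihood change
below 1e-5 or 100 iterations; hitting the cap is a logged warning, not an
error — on small-n data a near-empty component can drift geometrically
for a few hundred iterations without affecting `delta_hat` materially.

A weighted-least-squares companion estimate on the E–M classification
(classes by argmax responsibility, ties broken toward the null class),

    delta_WLS = [ sum_{C0} Delta_i/nu2_i0 + sum_{C1} (Delta_i−l1)/nu2_i1
                  + sum_{C2} (Delta_i−l2)/nu2_i2 ] / [ matching 1/nu2 sums ],

is nearly perfectly correlated with the E–M estimate and supplies a
variance estimate `Var(delta_WLS) = 1 / sum_i 1/nu2_{i,class}` (inter-taxon
covariances neglected; with m0 null taxa of equal variance v this is
v/m0, so the bias estimate's noise decays like 1/(n·m0)).

## Tests and intervals

Primary statistic (asymptotically standard normal under the null):

    W_i = (Delta_i − delta_EM) / sqrt(sigma2_i1 + sigma2_i2).

When sample sizes are modest or the non-null fraction is large, the
uncertainty in the bias estimate is not negligible and the conservative
variant is used:

    W*_i = (Delta_i − delta_WLS) / (sqrt(sigma2_i1 + sigma2_i2)
                                    + sqrt(Var_hat(delta_WLS))),

whose denominator upper-bounds the standard deviation of the numerator.
The `auto` rule selects W* when min(n1, n2) < 30 or the fitted non-null
mass pi1 + pi2 exceeds 0.5 — a documented heuristic, overridable.  In
simulation the plain W is calibrated from roughly n = 30 per group
(measured type-I error 0.051–0.052 at n = 30–50, about 0.07 at n = 20
because the n^-2 variance prefactor omits a degrees-of-freedom
correction); W* is conservative below that.

p-values are two-sided normal; multiplicity adjustment defaults to
Bonferroni (Holm and Benjamini–Hochberg selectable).  Simultaneous
confidence intervals use `effect ± z_{1−alpha/(2m)} · se` with the same
standard error as the chosen statistic, so an interval excludes zero
exactly when the Bonferroni-adjusted test rejects.

## Multigroup analysis

With g >= 3 groups, each non-reference group j is paired with the
reference r and the two-group mixture machinery yields `delta_hat_rj`.
De-biased means `mu*_ij = mu_ij + delta_hat_rj` (identity on r) are
comparable across groups up to one shared constant `dbar_r.`, which
cancels in every pairwise difference; the de-biased offsets
`d*_jk = d_jk − delta_hat_rj` recover the true log sampling fractions up
to the same constant (correlation with truth > 0.99 in the benchmark).
Pairwise statistics `W_{i,jj'} = (mu*_ij − mu*_ij')/sqrt(sigma2_ij +
sigma2_ij')` reuse the residual variances (de-biasing adds a constant per
group, leaving residuals unchanged).  The global null for a taxon is
tested with the maximum of absolute pairwise statistics against a
simulated null: B draws of independent standard normals per pair, same
max-of-absolutes, one shared null sample for all taxa (the null law
depends only on the number of pairs).  Absolute values are used on both
the observed and the null side for a coherent two-sided test; the raw-max
variant and an add-one p-value correction `(1 + #{>=})/(B + 1)` are
available behind flags.

**Finite-B caveat.**  Simulated-null p-values have resolution 1/B.  Fed
into a Bonferroni correction over m taxa, significance requires
p <= alpha/m, so with B < m/alpha the only achievable significant value
is p = 0, which means "beyond every null draw" and occurs with
probability m/(m + B) per family even under a perfect null (about 1/3 at
m = 500, B = 1000).  Choose B >= m/alpha — e.g. B = 10000 for m = 100 at
alpha = 0.05 — whenever the global test feeds a Bonferroni correction.

## Zero handling

Presence proportions `p_hat_ij` (fraction of non-zero samples) drive the
structural-zero rule: taxon i is declared structurally absent from group
j when `p_hat_ij = 0` or when the normal lower bound
`p_hat − 1.96·sqrt(p_hat(1−p_hat)/n_j)` is <= 0 (algebraically:
`p_hat <= z^2/(n_j + z^2)`; the multiplier is configurable).  A taxon
structurally absent in some groups is declared differentially abundant
against those groups without testing (p = 0 convention in the output,
`decided_by_structural_zero = True`), is excluded from bias estimation,
and is tested only among the groups where it is present; taxa absent
everywhere are dropped.  Remaining zeros are treated as sampling zeros
and imputed with a pseudo-count (default 1) on the raw count scale.
Outlier-zero detection is out of scope.  Note the presence rule is a
pure function of sparsity: in data where true mean counts drop to a few
reads per sample it will misclassify sampling sparsity as structural
absence, so interpret auto-decisions cautiously in very sparse strata.

## Synthetic-data generator

The benchmark draws

    theta_i1 ~ Uniform(50, 500)                     ecosystem means
    theta_i2 = theta_i1 · exp(±u), u ~ U(1, 2)      for 10% DA taxa,
                                                    direction 50/50
    A_ijk ~ Gamma(mean theta_ij, shape 2)           latent abundances
    d_jk ~ Uniform(per-group range)                 log sampling fractions
    O_ijk ~ Poisson(exp(d_jk) · A_ijk)              observed counts

so counts are negative-binomially overdispersed and zeros arise naturally
from the Poisson layer.  The balanced up/down split keeps total microbial
load roughly balanced, so group confounding of sampling fractions comes
only from the designed `d` ranges.  Scenario presets: **large**
variability uses disjoint per-group ranges — (−1.5, −0.5) vs
(−2.5, −1.5) for two groups; for g > 2 the same total span (−2.5, −0.5)
is partitioned into g disjoint sub-ranges, keeping counts in the regime
the log-linear model assumes — **moderate** shifts a width-1 window by
−0.5 per group (overlapping), **small** reuses one window everywhere (no
confounding).  All parameters are overridable; everything is
deterministic given (seed, config).

What the generator does *not* emulate: taxon–taxon correlation,
phylogenetic structure, heavy-tailed (log-scale) abundance distributions,
batch effects, or library-size-targeted sequencing.  Passing benchmarks
here therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to every feature of real data.
One consequence worth knowing: with uniform(50, 500) base means the
log-library-size baseline is only mildly penalized by load imbalance, so
the residual-diagnostic margin over TSS is driven by the DA-induced load
shift, which is exactly the mechanism the method corrects.

The FDR/power harness runs the full pipeline per replicate and counts a
taxon as discovered when its adjusted p-value is at or below alpha or the
structural-zero pattern decided it; FDR is the mean false-discovery
proportion, power the mean true-positive fraction among DA taxa.

## Diagnostics

`sampling_fraction_residuals` scores any per-sample offset estimate
against the generator's truth.  Since every estimator recovers log
sampling fractions only up to an additive constant, residuals are
centered by subtracting the estimator's **overall** mean residual; the
reported variance and the group-separation score (max difference of group
mean residuals) then expose both noise and group-level bias.  A
within-group-centered version is also returned for pure-noise
comparisons.  The TSS baseline is the centered log library size.

## Problem sizes used in the test suite

Simulation-backed tests use m = 100–500 taxa, n = 15–200 per group, and
15–100 replicates, chosen to put Monte-Carlo error well inside each
asserted band; estimator-level studies (bias, correlation, variance
scaling) run on the mixture directly rather than through count data, as
the claims concern the mixture-stage estimators.

## Known limitations

* No covariate adjustment, repeated measures, or longitudinal designs.
* Type-I error of the plain W statistic is inflated below ~n = 30 per
  group (no df correction, as defined); use W* (the default there).
* The structural-zero rule misfires at very low mean counts.
* The global test's Bonferroni step needs B >= m/alpha null draws.
* Inter-taxon correlation is ignored when estimating the bias (working
  independence); strongly correlated communities may widen the true
  sampling distribution of delta_hat relative to its estimate.
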
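# Methods

## Effect sizes

The per-study effect for a gene is the log fold change (LFC): the case
minus control difference of mean log2 expression. Its sampling variance is
the Welch-style variance of a mean difference,
`s²_case/n_case + s²_control/n_control`, with unbiased (ddof = 1) group
variances. This is the standard variance for an unpaired mean difference
on the log scale and is what inverse-variance pooling requires. No
moderated or empirical-Bayes shrinkage is applied: plain sample variances
keep each study's contribution auditable. A variance of exactly zero
(both groups constant, which occurs only in degenerate toy inputs) is
floored at `1e-8` with a logged warning so weights stay finite.

Input matrices are expected on the log2 scale. A matrix whose maximum
exceeds 50 is judged to hold linear-scale intensities and transformed as
`log2(x + 1)`: log2 microarray data top out well below 20 while linear
intensities reach the hundreds, so the threshold separates the two regimes
cleanly; the `+1` avoids −∞ at zero. No cross-sample normalisation
(quantile, median-centring) is applied — only the scale transform — since
the pooling operates on within-study contrasts, which are invariant to
per-study additive shifts. Duplicate gene identifiers (probe redundancy)
are collapsed to the single row of highest mean expression, ties keeping
the first occurrence. Gene rows containing missing values are dropped per
study; the pooling layer already tolerates genes absent from some studies,
so imputation is unnecessary.

## Cohort selection

A cohort qualifies for pooling when it is a *series* entry of an *RNA
expression* study on *Homo sapiens* with a case/control design and at
least 10 samples in total. Records failing or lacking a criterion are
excluded with a machine-readable logged reason. The packaged eleven-cohort
catalogue (358 cases / 278 controls, seven countries, study ages 2–13
years) passes the filter in full and doubles as the default simulation
design.

## Pooling and heterogeneity

Per gene, with effects `y_i` and variances `v_i`:

- fixed-effect pool: inverse-variance mean, `SE = sqrt(1/Σw_i)`;
- Cochran's `Q = Σ w_i (y_i − μ̂_F)²`, `df = k − 1`;
- `I² = (Q − df)/Q × 100`, clamped to 0 when `Q ≤ df`;
- `p_Q`: upper chi-square tail of Q at df — the probability that the
  observed dispersion is within-study sampling only;
- model rule: fixed iff `Q ≤ df`, else random effects with the
  (non-iterative) DerSimonian–Laird `τ̂² = max(0, (Q−df)/(S₁−S₂/S₁))` and
  weights `1/(v_i + τ̂²)`. DL is the canonical moment estimator matching
  the Q-based selection logic; iterative alternatives (REML,
  Paule–Mandel) and the Hartung–Knapp adjustment are out of scope.

The model rule is applied *per gene*; a config flag is not provided to
make it global because a single global choice does not scale to hundreds
of genes with differing heterogeneity. Two-sided p-values use the normal
approximation `z = μ̂/SE`; a Student-t option with `df = k − 1` is
available (`use_t=True`) and is known to be more conservative at small k
(see Limitations). 95% CIs are `μ̂ ± 1.96·SE`. The reported `std_lfc` is
the between-study sample standard deviation of the per-study LFCs — an
interpretation choice, since "spread of study effects" admits several
readings; it is exported so users can compare alternatives.

A gene enters the pooled results only when measured in a majority of the
qualifying cohorts: at least `max(2, ceil(min_fraction × N))` studies with
`min_fraction = 0.5` (6 of 11 in the default design). Significant genes
satisfy `p < 0.005` and `|LFC| > 1` on the raw p-value; a
Benjamini–Hochberg FDR column is emitted for information but never used
for filtering, matching the raw-p convention of the filter.

## Gene-list overlap

The overlap of two gene lists (identifiers uppercased and stripped; no
alias mapping) is tested with the one-sided hypergeometric upper tail
`P(X ≥ k)` — the enrichment-direction Fisher exact test. The universe size
is a required analytical choice; the default of 20,000 protein-coding
genes is a convention, and the p-value depends strongly on it (counts and
percentages do not). A two-sided variant doubles the smaller tail.

## Meta-regression

Per-study LFCs of one gene are regressed by unweighted OLS on an
intercept, total sample size, region indicators and study age. With ~11
studies, country-level dummies (7 levels) would exhaust the residual
degrees of freedom, so countries are grouped into broad regions (default
Asia / Europe / North America, Europe as reference; configurable).
Constant covariate columns are dropped with a log note; a rank-deficient
design after that guard is a hard error. Inference is t-based with
`df = n − p`. An inverse-variance weighted option is deliberately absent
from the default path: the regression models the study-level effect, and
unweighted OLS is the plain multiple-linear-regression reading.

## Synthetic-data generator

The generator draws, for gene *g* in study *i*,
`θ_gi ~ N(true_lfc_g, τ²)`, control samples `N(baseline, σ²)` and case
samples `N(baseline + θ_gi, σ²)` — exactly the Normal/Normal hierarchy the
pooling estimators assume, so calibration checks are meaningful. Defaults:
the eleven-cohort catalogue for group sizes, `σ² = 1.0` (a typical
per-gene log2-scale variance for expression arrays), `baseline = 8.0`
(mid-range log2 intensity), `τ² = 0`, full gene coverage. Coverage < 1
removes a without-replacement random gene subset per study, emulating
platform differences; a configuration leaving a gene measured nowhere is
rejected. One master `SeedSequence` spawns per-study substreams, so
appending studies never perturbs earlier ones and identical configs are
bit-identical.

What the generator does *not* emulate: probe-level structure, batch and
lab effects, heavy-tailed or gene-correlated noise, platform-specific
intensity distributions, and label noise. Passing calibration tests on
this generator therefore validates the estimators under their own
assumptions; it does not certify behaviour on real arrays, where
normalisation choices and annotation reconciliation dominate.

For placing simulations in a prescribed heterogeneity regime,
`tau2_for_target_isq` solves the moment identity
`E[Q] = df + τ²(S₁ − S₂/S₁)` for τ², which equals choosing the population
I² `τ²/(τ² + s²_typical)` with `s² = (k−1)S₁/(S₁² − S₂)`. Note the
finite-sample mean of the clamped I² *statistic* sits below the population
value (≈42% observed when the population value is 46% at k = 11), a
property of the statistic, not of the calibration.

## Numerical choices and scale

- Problem sizes used by the shipped checks: 500 replicates for coverage
  and Q-calibration runs, 20,000 genes for the type-I-error run, 100
  random instances per estimator for oracle comparisons — sizes at which
  Monte-Carlo standard errors are small relative to the asserted bounds
  while a full run stays interactive.
- Vectorised pooling (`meta_analyze`) and the scalar path
  (`meta_analyze_gene`) are algebraically identical and tested to agree to
  1e-10; the vectorised path handles partial coverage via masked arrays.
- Tie-breaks: duplicate-gene collapse keeps the first row on tied means;
  result tables sort significant genes by p ascending with stable order.

## Limitations

- The z-based 95% CI ignores the sampling noise of τ̂². At k = 11 and
  moderate heterogeneity (population I² ≈ 46%) its measured coverage is
  ≈92.4% rather than 95% (with the true τ² plugged in the same interval
  covers ≈94.8%; a t(k−1) quantile gives ≈95.3%). This is the classic
  DerSimonian–Laird plug-in deficit that Hartung–Knapp-type corrections
  address; `use_t=True` is the available mitigation.
- The normal-approximation p-value is mildly anti-conservative at small
  group sizes (null `p < 0.005` rate ≈0.006 under the default design);
  the joint filter with `|LFC| > 1` is far stricter in practice.
- The hypergeometric p-value is only as meaningful as the chosen universe.
- No multiple-testing correction is applied to the significance filter by
  design; the FDR column is informational.
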
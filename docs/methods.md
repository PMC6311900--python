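# Methods

## Setting

`mr2sample` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. Genetic variants serve as instrumental variables for an
exposure: because alleles are assigned at meiosis independently of later
environment, a variant that (1) associates with the exposure, (2) is
independent of confounders, and (3) affects the outcome only through the
exposure identifies the causal effect of the exposure on the outcome. In
the two-sample design the variant–exposure effects `beta_x[j] ± se_x[j]`
and variant–outcome effects `beta_y[j] ± se_y[j]` come from different
cohorts and are combined at the summary level. For binary traits all
effects are log odds ratios per effect allele.

The packaged worked dataset is the published analysis of Parkinson's
disease (PD) as exposure and Alzheimer's disease (AD) as outcome: 39
harmonized instruments from large PD and AD case–control GWASs, plus the
seven SNCA-locus candidate variants used for a single-instrument analysis
of alpha-synuclein.

## Harmonization

Matching is by rsID; coordinates are metadata. Outcome records reported on
the swapped allele pair (or its strand complement) have their beta negated
and frequency complemented. Palindromic variants (A/T, C/G) cannot be
strand-resolved from alleles; the default policy `infer-by-eaf` orients
them by comparing allele frequencies and excludes the variant when **both**
frequencies lie within `eaf_window = 0.08` of 0.5 (ambiguous zone
0.42–0.58). The "both" rule is a deliberate reading — one informative
frequency is useless without a comparable one on the other side, so the
pairwise comparison is only hopeless when both are near 0.5; users wanting
stricter behaviour can set `palindrome_policy="drop"`. Variants with a
missing frequency fall back to `drop` when palindromic and to plain allele
matching otherwise. Harmonization is idempotent and records every
exclusion with a reason (`missing-in-outcome`, `allele-mismatch`,
`palindromic-ambiguous`, ...).

## Estimators

With weights `w_j = se_y[j]^-2`:

* **IVW**: `theta = sum(w*bx*by) / sum(w*bx^2)`, the weighted regression of
  `beta_y` on `beta_x` through the origin. Fixed-effect SE
  `sum(w*bx^2)^-1/2`; the multiplicative random-effects model scales it by
  `max(1, sqrt(Q/(J-1)))`, with `Q` Cochran's heterogeneity statistic.
  `model="default"` resolves to fixed for J ≤ 3 and random otherwise,
  mirroring common reference software.
* **MR-Egger**: the same regression with a free intercept after orienting
  every variant to `beta_x > 0`. The intercept estimates the average direct
  (pleiotropic) effect per variant; the slope is the
  pleiotropy-adjusted causal effect. Both SEs carry the residual inflation
  factor `max(1, sqrt(RSS_w/(J-2)))`. p-values are two-sided normal by
  default; the J−2 t-reference is available via `distribution="t"` but is
  not the default.
* **Weighted median**: per-variant ratios `by/bx` are ordered (ties broken
  by rsID so results are permutation-independent), weighted by inverse
  second-order ratio variances
  `se_y^2/bx^2 + by^2*se_x^2/bx^4`, and the weighted 50th percentile is
  interpolated at the cumulative-weight midpoints. The SE is a parametric
  bootstrap (default `n_boot = 1000`, `seed = 42`): `(beta_x, beta_y)` are
  redrawn from their normal sampling distributions and the median
  recomputed. The point estimate never depends on the seed.
* **Maximum likelihood**: `beta_x[j] ~ N(xi_j, se_x[j]^2)`,
  `beta_y[j] ~ N(theta*xi_j, se_y[j]^2)` jointly over `(theta, xi)`. The
  latent `xi_j` have a closed-form optimum for fixed theta, so the profile
  negative log-likelihood `sum((by - theta*bx)^2 / (se_y^2 +
  theta^2*se_x^2))/2` is minimized by damped Newton iteration
  (initialized at the fixed-effect IVW estimate, curvature by central
  difference, convergence when the step falls below `tol*(1+|theta|)`,
  default `tol = 1e-8`, cap 10^4 iterations). The SE comes from the
  observed information of the full likelihood, profiled onto theta via the
  Schur complement.
* **Wald ratio** (single instrument): `by/bx`, first-order SE `se_y/|bx|`
  or the default delta-method SE adding the exposure-uncertainty term.

All estimators are invariant to variant permutation and to joint
orientation flips, sign-equivariant in the outcome and scale-equivariant
in the exposure; the test suite checks these properties and 10-decimal
agreement of IVW/Egger with explicit-summation weighted least squares.

## Screening

Tag-SNP selection at a locus filters reported lead SNPs to an allowed
discovery ancestry (default European/Caucasian), links candidates with LD
`r^2 >= 0.2` to the locus reference into one group (r² values are inputs,
e.g. from an LD browser; never computed here), and keeps the member
reported by the largest study. The packaged candidate table carries
approximate published cohort sizes — only their ordering matters.

The confounder screen excludes any instrument with an association
`p < threshold` to a confounder trait, staged 1–4 (education/lifestyle,
diet, alcohol, outcome biomarkers); stage 5 is the Egger intercept test in
the sensitivity module. The published analysis never states its
significance cutoff; the default `threshold = 1e-3` is the loosest value
consistent with every exclusion it reports (flagged p-values span 6.42e-4
to 1.95e-9) and with no non-exclusion, and a single sub-threshold hit
suffices (strict inequality; the strict single-hit rule is likewise the
one that reproduces the reported instrument set).

## Synthetic data and calibration

The generator draws exactly from the maximum-likelihood model plus an
optional per-variant direct effect `alpha_j ~ N(pleio_mean, pleio_sd^2)`.
Defaults emulate the packaged dataset's regime: J = 39, true exposure
effects `|N(0.11, 0.05^2)|`, exposure SEs uniform on [0.009, 0.057] and
outcome SEs on [0.016, 0.086] (the packaged table's extremes). Replicate r
of a calibration experiment uses seed `root_seed + r`, so streams are
reproducible and independent. The generator does not model LD between
instruments, selection on genome-wide significance (winner's curse), or
sample overlap between cohorts; calibration results therefore validate the
estimators under their own assumptions, not those survey artefacts.

Calibration checks run in the test suite at sizes chosen to keep the whole
suite fast while leaving Monte-Carlo error well below the tested margins:
1000 null replicates for the IVW type-I error (3-sigma binomial band
around 0.05), 500 replicates for Egger-intercept recovery of an injected
directional pleiotropy of 0.05. Intercept recovery is asserted in a
strong-instrument configuration (`gamma_mean = 0.3`, `se_x` in
[0.005, 0.01]) because exposure measurement error attenuates the fitted
slope and thereby biases the intercept — a known property of the
regression, visible in the default moderate-strength regime, not an
implementation artefact.

## Reproduction of the published analysis, and a known inconsistency

`mr2sample reproduce` (or `cli_report.reproduce_analysis`) regenerates the
estimator table, leave-one-out table, per-variant forest data, tag-SNP
audit, screen report and a comparison file against every published value.

The published per-variant table is internally consistent (its outcome
betas, SEs and p-values agree), and quantities driven by z-statistics
reproduce well: the IVW p-value (0.287 recomputed vs 0.291 published) and
the leave-one-out IVW p-values (0.992 vs 0.991 excluding rs356182; 0.115
vs 0.117 excluding rs35749011 — residual differences at the third decimal
are consistent with the publication analyzing unrounded inputs while
printing three decimals). The published *odds ratios*, however, are not
derivable from the published per-variant effects by any standard
estimator: every published log odds ratio — IVW, maximum likelihood, and
the single-instrument Wald ratio alike — is a near-constant 2.27–2.29
times the value recomputed from the printed inputs, indicating that the
published analysis used exposure effects on roughly 0.44× the printed
scale (the printed near-zero Egger intercept argues the rescaling was on
the exposure side). The clearest case is the single-instrument result:
`exp(-0.056/0.285) = 0.821`, not the published 0.638. This package does
not force agreement; the comparison file reports recomputed values next to
published ones with the discrepancy flagged, and the estimators remain
faithful to the printed inputs. The published weighted-median estimate
(1.069, with a confidence interval not even log-symmetric about it) is on
the wrong side of 1 relative to the printed inputs under any positive
rescaling and appears unreproducible outright.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `palindrome_policy` / `eaf_window` | `infer-by-eaf` / 0.08 | palindrome handling; ambiguous zone 0.42–0.58 |
| IVW `model` | `default` | fixed if J ≤ 3 else multiplicative random effects |
| weighted median `n_boot`, `seed` | 1000, 42 | bootstrap SE only; point estimate seed-free |
| ratio SE order | second | delta-method including exposure uncertainty |
| ML `tol`, iteration cap | 1e-8, 10^4 | Newton step tolerance on theta |
| screen `threshold` | 1e-3 | strict single-hit confounder exclusion |
| tag selection `r2_link_threshold` | 0.2 | LD linkage into one group |
| leave-one-out seeds | `seed + row` | independent, reproducible rows |
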
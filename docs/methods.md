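# Methods

This note documents the statistical procedures, their assumptions, the
defaults, and the choices made where the design was genuinely open.

## Survey model and recall-period years

A recall survey yields one row per fisher × career period. Periods are the
first and last three-year windows of the career plus, for careers longer
than 10 years, a mid-career year. Calendar years are assigned by a midpoint
convention: `first = start + 1`, `last = end − 1`, `mid = ⌊(start+end)/2 + ½⌋`
(round half up — the convention is deterministic; nothing in the data
distinguishes the two candidate years of an even-length career). Careers
shorter than three years collapse both windows to the single career
midpoint; the survey instrument does not define behaviour there, so the
package picks the only symmetric option. All years are calendar integers.

Validation is report-based (a list of located violations, empty on clean
data) rather than exception-based, so a whole file can be audited in one
pass.

## Trend reconstruction

Response: log catch per typical trip. Fixed-effect candidates: year,
gillnet length, fishing time, all standardized to mean 0 / sample SD 1
(ddof = 1, the R `scale()` convention); the fitted transform is stored and
reused at prediction time. Random structure: intercept per fisher. The
model assumes multiplicative (lognormal) catch errors and an approximately
log-linear historical trend; it describes past trends only and must not be
extrapolated.

- **Model set.** All 2³ subsets of the main effects, in deterministic
  order. An optional policy adds two-way interactions containing year,
  subject to marginality. Interactions between the two effort/gear
  covariates are not offered: they address a question (effort synergy) the
  trend analysis does not ask.
- **Estimation.** statsmodels `MixedLM`. Optimizer: lbfgs with bfgs/powell
  fallbacks (the intercept-only profile surface is occasionally singular
  for lbfgs). Boundary fits (`var_fisher → 0`) are reported with a
  `singular` flag, not treated as errors. A singular random-effect
  covariance (e.g. a constant response) falls back to the marginal
  fixed-effect fit for fitted values.
- **AIC.** REML likelihoods are not comparable across fixed-effect
  structures, so by default each candidate is refitted by maximum
  likelihood for its AIC (`−2ℓ + 2k`, `k` = fixed effects + 2 variance
  components) while coefficients are reported from REML. A
  `strict_reml_aic` flag compares REML AICs literally for users who want
  the as-described behaviour of common mixed-model averaging workflows.
  Plain AIC is the default; note that some model-averaging tools default to
  AICc — with 500+ observations and ≤ 6 parameters the difference is
  negligible, but the choice is surfaced here rather than silently made.
- **Averaging.** Members: ΔAIC < 4 (configurable). Weights
  `w ∝ exp(−Δ/2)`. Full (zero-substituted) averaging; unconditional
  standard error `√(Σ w_m (se_m² + (β_m − β̄)²))`; 95% intervals use the
  normal multiplier 1.96. Conditional averaging was rejected as the default
  because it biases averaged effects away from zero when weak models are in
  the set.
- **Prediction.** Covariates other than year sit at their standardized mean
  (0), so only intercept and year columns contribute. Each member predicts
  with its own fixed-effect covariance; the averaged band combines
  within-member variance and between-member spread, then exponentiates.
  Back-transformation is naive exponentiation (no smearing correction);
  the band is a coefficient-propagated confidence band for the population
  median trajectory, not a prediction interval for individual trips.
- **Diagnostics.** (1) linearity: t statistic of a quadratic term in a
  residual-vs-fitted regression; (2) normality: Shapiro–Wilk on residuals;
  (3) independence: lag-1 autocorrelation of residuals within fisher,
  ordered by year; (4) collinearity: VIF per fixed term (1 by convention
  for a single term; values above 10⁶ reported as ∞ and flagged).

## Composition clustering

Rows are fisher × period responses over the top-12 species by total
reported catch (ties at the cutoff break toward the lexically smaller
species id and are warned). Values are per-species catch in kg by default;
a proportion mode row-normalizes instead (all-zero rows are excluded and
counted). kg mode is the default because cluster follow-ups compare catch
magnitudes per species; with a strong overall decline the kg matrix also
carries the trend signal, which is exactly what the time-vs-cluster ANOVA
is meant to detect.

- **Distance/clustering.** Manhattan distance; PAM k-medoids (BUILD
  initialization, best-improvement SWAP; all ties toward the lowest row
  index). Instances with ≤ 2000 candidate medoid subsets are solved
  exactly by enumeration — single-swap local search cannot guarantee the
  global optimum, and on small instances exactness is cheap. Centroid
  k-means cannot consume a precomputed distance matrix, which is why
  k-medoids is the primary algorithm; Euclidean k-medoids is available via
  the estimator's `metric` parameter.
- **Choosing k** (grid 1–10): elbow = maximum second difference of the
  within-dissimilarity curve; silhouette = maximum mean width (singleton
  clusters score 0); gap statistic per the original formulation — reference
  rows uniform over each column's observed range, B = 50 seeded draws,
  `SE = sd·√(1+1/B)`, choose the smallest k with
  `gap(k) ≥ gap(k+1) − SE(k+1)`. Consensus = majority of the three, ties
  resolved by the silhouette choice (it is the only criterion with an
  absolute scale). The within-dissimilarity curve is made nonincreasing by
  warm-starting k+1 from the k solution plus the best greedy addition and
  keeping the better of warm and cold runs.
- **Cluster tests.** One-way ANOVA of assigned year by cluster with Tukey
  HSD; MANOVA via Pillai's trace computed from between/within cross-product
  matrices with the standard F approximation, plus univariate per-species F
  follow-ups. Pillai's trace was chosen for its robustness to mild
  covariance heterogeneity; a singular total cross-product matrix raises
  with guidance to drop collinear columns.
- **Summaries.** Per cluster: median year, mean composition, dominance
  (largest share of the normalized mean composition) and Pielou evenness
  (`−Σp ln p / ln S` over nonzero shares; 0 for a single-species
  composition). The funnel flag is true when dominance strictly decreases
  across clusters ordered by median year.

## Length-based status

The three empirical regressions (see README) are stored in one versioned
constants table. Total length is assumed throughout; no fork/standard
length conversions are applied. Ratios are rounded half-up to 2 decimals
for reporting and classification (matching how such tables are published);
full precision is retained internally. Classification boundaries close the
gaps in the published class definition — ratio ≥ 1.00 healthy,
ratio ≤ 0.53 seriously overexploited, otherwise overexploited — and are
configurable. External Lm/Lopt always take precedence over the empirical
chain; the bundled worked example ships back-derived external Lm values
(flagged in `datasets.BACK_DERIVED_LM`) for the five species whose
published ratios are not reproducible from Lmax alone. Species lacking both
Lmax and external lengths are labeled `unassessed` and excluded from class
summaries.

## Synthetic fishery generator

The generator emulates the data structure the analyses assume, with known
ground truth for recovery testing:

- careers uniform over 1959–2020 (lengths 3–60 y); periods via the midpoint
  convention;
- log catch = baseline + β_year·z(year) + β_time·z(hours) + β_net·z(net) +
  fisher intercept + lognormal noise. Defaults: 200 fishers,
  β_year = −0.5, β_time = 0.2, β_net = 0.1, σ_fisher = σ_resid = 0.3,
  baseline 3.0 (≈ 20 kg) — a strong multi-decade decline with realistic
  recall scatter. Standardization uses the realized sample, so true
  coefficients live on the analysis scale;
- covariates lognormal around 6 h trips, 100 m nets, 2.1 cm mesh;
- per period, a composition is drawn from a Dirichlet whose concentration
  interpolates from a concentrated early era (8, 1, …, 1) to a uniform late
  era (the funnel mechanism); the five largest shares become the reported
  species, renormalized so species catches sum to the multispecies catch
  (a discard-the-remainder mode is available);
- length-at-catch starts at 1.1 × Lm and declines by 50% across a career,
  with 5% lognormal noise — stocks drift from marginally healthy to
  seriously overexploited;
- one root seed with per-fisher substreams: adding fishers never perturbs
  earlier fishers' draws.

What it deliberately does **not** model: recall biases (telescoping,
heaping, motivated misreporting), gear selectivity curves, seasonal
structure, or species interactions. Passing recovery tests therefore shows
the *pipeline* is consistent — not that real recall data are unbiased.

## Problem sizes in the tests and acceptance script

Recovery studies use 200 fishers × 100 seeds (test suite) and × 30 seeds
(acceptance script); cluster-count recovery uses 3 × 20 Dirichlet rows over
12 species × 50/20 seeds with gap B = 50; funnel checks use 60 fishers.
These sizes give stable proportions while keeping a full run in minutes on
one CPU.

## Known limitations

- Recall error is treated as lognormal measurement noise; systematic recall
  bias would bias trend magnitudes and cannot be detected internally.
- The ΔAIC < 4 averaging set is computed on ML refits by default; strict
  REML comparison is available but not recommended.
- Confidence bands on back-transformed trends are coefficient-propagated,
  not simulation-based prediction bands.
- PAM above the exact-enumeration threshold is a local search: optimal in
  all tested small instances, but without a global guarantee.
- The empirical life-history chain carries the (unpropagated) uncertainty
  of its source regressions; status labels near class boundaries should be
  read accordingly.
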
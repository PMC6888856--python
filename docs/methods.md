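# Methods

`lagshift` re-creates, on fully synthetic data with known ground truth, an
analysis chain that links abrupt change in remotely sensed vegetation
activity to local biodiversity: per-site monthly EVI series are screened for
a single structural break, the break is summarized by three attributes
(magnitude shift, trend difference, time passed before biodiversity
sampling), and site-level biodiversity measures are compared between changed
and unchanged sites with paired hierarchical models and compositional
similarity summaries. This note documents the models, the parameter choices
and their rationale, the numerical decisions, and what the synthetic data do
and do not establish.

## 1. The time-series model and break detection

Each monthly series ȳ_t is modelled as a piecewise-linear trend plus an
annual harmonic seasonal term of order k:

    ȳ_t = α_s + β_s t + Σ_{p=1..k} [a_p sin(2πpt/12) + b_p cos(2πpt/12)] + ε_t

with segment-specific intercept and slope (s ∈ {1, 2}) and seasonal
coefficients shared across segments: the break affects level and trend, not
phenology. The linear sine/cosine parameterization is equivalent to
amplitude–phase pairs (γ_p, δ_p), recoverable via
γ_p = √(a_p² + b_p²), δ_p = atan2(b_p, a_p).

**Breakpoint search.** The single most influential break is the candidate
month minimizing the total residual sum of squares of the two-segment fit,
scanned exhaustively over all admissible candidates (each segment must keep
at least `min_segment_months = 12` non-missing observations). The scan is
exact: the two break columns (level step, slope ramp) are orthogonalized
against the QR basis of the no-break design, so each candidate costs O(np)
while reproducing the full OLS refit to machine precision (verified against
an exhaustive-refit oracle in the tests). RSS ties break to the earliest
admissible month. Missing months are dropped row-wise, never imputed.

**Decision rule.** A break is reported only when two conditions hold
(conjunction; `require_bic=false` gives MOSUM-only behaviour):

1. an OLS-MOSUM test on the no-break residuals rejects at α = 0.05. The
   statistic is the supremum over windows of ⌈h·n⌉ consecutive residuals of
   the absolute scaled moving sum, with the bandwidth h = 12 months divided
   by the series length (one year of data relative to the record). P-values
   come from a Monte-Carlo table of the statistic under i.i.d. Gaussian
   residuals (2000 draws per (n, window) pair, fixed internal seed, cached).
   Using raw-noise tables for regression residuals is slightly conservative
   — measured size ≈ 3% at nominal 5% on clean seasonal series — which is
   the safe direction for a screening step;
2. the one-break BIC improves on the no-break BIC, with Gaussian profiled
   variance and parameter counts 2 + 2k + 1 (no break) versus three more
   (extra intercept, slope and the break position).

**Seasonal fallback.** When the harmonic design is rank-deficient (e.g.
observations concentrated in few calendar months) the seasonal component is
removed by a periodic decomposition — backfitting a linear trend and
centred month-of-cycle means, the periodic limit of a loess-smoothed
seasonal, tolerant of missing months — and a trend-only (k = 0) model is
fitted. The fallback needs at least two full years of observations.

**Invariances.** Adding a constant to a series or scaling it by c > 0
leaves the estimated break month and the MOSUM p-value unchanged;
both are covered by tests.

## 2. Change attributes and bins

For a reported break at month t_j:

- **magnitude** = (ŷ_j − ŷ_{j−1}) / |ŷ_{j−1}|, with ŷ evaluated from the
  *trend component only* (post-break segment at t_j, pre-break segment at
  t_j − 1). Including the seasonal term would contaminate the immediate
  change with month-to-month phenology; a `magnitude_from="full"` switch
  restores the trend-plus-seasonal reading. Pre-break levels below 1e−6 in
  absolute value make the ratio undefined; such sites are flagged and
  excluded.
- **trend difference** = β_after − β_before (EVI/month).
- **time passed** = t_n − t_j in months, where t_n is the start of
  biodiversity sampling. A negative value (break after sampling began)
  demotes the site to unchanged for that sampling event.

Bins use inclusive upper edges matching their labels: |magnitude| at 0.25
and 0.50 with the sign giving loss/gain; |trend difference| at 0.01 and
0.05 EVI/month; time at [0, 60), [60, 120] and (120, ∞) months. A magnitude
of exactly 0 with a reported break falls in "gain ≤25%". Unchanged sites
carry the label `UC` in every bin field.

## 3. EVI preprocessing

Order is fixed: cloud/negative masking of the buffer-mean observations →
MAD outlier screening of the surviving values → monthly maximum-value
compositing → gap truncation.

- EVI2 = 2.5(NIR − Red)/(NIR + 2.4·Red + 1); reflectances outside [0, 1]
  are rejected. EVI exactly 0 is kept; only strictly negative values
  (snow/water) are masked.
- The MAD rule flags a value when its absolute deviation from the series
  median exceeds two *unscaled* MADs (no 1.4826 consistency constant — the
  threshold is deliberately conservative), or when the deviation lies
  strictly above the 99th percentile of all deviations. The forced top-1%
  rule is applied at most once per series (flag-guarded), per series rather
  than globally, and skipped below 24 finite values, where it would always
  delete data. A constant series (MAD = 0) falls back to the top-1% rule
  with a warning. Known limitation: on strongly peaked seasonal waveforms
  (sharp multi-harmonic cycles) the 2-MAD band can clip genuine seasonal
  maxima; with a single-harmonic annual cycle of amplitude 0.15 and noise
  0.03 the measured false-removal rate is ≈1%.
- A run of ≥60 consecutive missing months truncates the series to January
  1999 onward (the consolidation point of the synthetic archive's calendar,
  mirroring the sparse early-Landsat era).

**Site table.** Missing sampling extents (MLE, metres) are interpolated as
the mean over sites sharing (taxon group, sampling method), falling back to
the taxon-group mean; a hold-out validation (default 25% of reported MLEs
removed at random) reports the Pearson correlation between held-out truth
and interpolation. Sites with MLE > 3000 m (3000 itself is kept) or without
a usable series after truncation are dropped, with logged counts. Wholesale
exclusions (e.g. water-masked studies) enter as a generic study-id exclusion
list rather than GIS operations.

## 4. Biodiversity measures

- **Richness**: count of species with positive abundance or presence.
- **Abundance**: log10(total/relative effort + 1), relative effort being the
  site's effort divided by the maximum within its study (so in (0, 1]).
  The +1 offset admits empty assemblages and is configurable.
- **Evenness**: arcsine-square-root of Hurlbert's PIE,
  (N/(N−1))(1 − Σ p_i²) — the probability that two individuals drawn
  without replacement are different species. N ≤ 1 yields a missing value.
  With effort-adjusted non-integer totals the finite-sample factor uses the
  adjusted N.
- **Turnover**: Sørensen similarity 2a/(2a + b + c) on presence/absence,
  over all unordered site pairs within the same (study, land use) group.
  Occurrence-only studies contribute to richness and Sørensen, never to
  abundance or PIE.

PIE and Sørensen are verified against brute-force enumeration oracles to
1e−12 on 1000 random assemblages.

## 5. Hierarchical models

Responses are modelled separately: richness with a Poisson log-link GLMM
plus an observation-level random intercept (OLRE) absorbing
overdispersion; log abundance and asin-sqrt PIE with Gaussian LMMs. The
binned attribute enters as a fixed factor with UC as reference; studies
containing only unchanged sites are excluded (they carry no within-study
contrast). All fits are maximum likelihood, never REML, so AICs and LRTs
are comparable.

**Estimation.** The engine (``lagshift.glmm``) handles independent scalar
random effects (study, block, land-use, climate intercepts; a
change-presence random slope within study; the OLRE). For fixed variance
parameters the conditional mode of (β, b) is found by penalized IRLS on
sparse matrices; the marginal likelihood is the Laplace approximation at
that mode (exact for Gaussian responses, where it reproduces statsmodels
MixedLM to four decimals). Variance parameters are profiled by Nelder-Mead
on the log-SD scale with tolerances (xatol 0.01, fatol 2e−3) far below the
statistical uncertainty of the estimates. One deliberate approximation: β
is not moved along the gradient of the Laplace log-determinant term, so
against lme4's glmer the contrast coefficients agree to ~1e−6 while
intercepts can differ by ~1e−2 on small samples (cross-checked in the test
suite). SD estimates reaching the lower boundary (1e−3) are reported as 0
with a singular-fit warning. A deliberately simple two-stage alternative —
study-wise GLM contrasts pooled by inverse variance — is provided as
``fit_two_stage`` for cross-checks; the mixed model is the primary
estimator.

**Inference.** Random structures are compared by AIC on intercept-only
fixed designs over a nested candidate list (study; +block; +land use;
+presence slope; +climate), ties going to the fewer-parameter structure.
Full-versus-null LRTs use the χ² reference with df equal to the parameter
difference; per-bin Wald z tests are reported unadjusted across bins (no
multiple-testing correction, stated deliberately). Effects are
back-transformed to percent differences versus UC: 100(e^β − 1) for the
log link, 100(10^β − 1) on log10 abundance, and for PIE the percent change
of sin²(·) evaluated at the reference fitted value, each with delta-method
standard errors. Magnitude and trend models of the same response are
compared by |ΔAIC| and the Pearson correlation of severity-matched bin
effects.

## 6. Composition summaries

Pairwise Sørensen values are averaged into a symmetric bin × bin matrix
(unweighted across pairs by default; a study-weighted mean-of-study-means
variant is available), expressed relative to the UC–UC mean, and the bin
rows are clustered by complete linkage on Manhattan distances. Cells
without pairs are missing; distances between rows renormalize the
Manhattan sum by the number of shared finite cells, and a bin missing
everywhere is dropped from the clustering. The merge tree is serialized
with deterministic left-child ordering by label.

## 7. The synthetic landscape generator

The generator defines the study conditions; every default was chosen once,
for realism, and the tests run against those conditions.

- **Scale**: 40 studies × 30 sites by default (the scale at which parameter
  recovery is assessed); each study keeps at least one unchanged reference
  site. Land use ∈ {PV, SV, HDV}; climate zone, taxon group and a
  taxon-appropriate sampling method per study; 2–4 spatial blocks.
- **EVI series**: monthly span 1998–2015 (216 months), baseline 0.30–0.60
  EVI, background trend ±3e−4 EVI/month, two-harmonic seasonal cycle of
  amplitude 0.15 (second harmonic at 0.3 relative weight), Gaussian noise
  0.03, three raw observations per month, 15% cloud-flagged, 2% spike
  outliers, and a 6-month missing block at 30% of sites. Breaks fall
  uniformly in 2000–2013 with magnitude ±0.6 and trend difference ±0.004
  EVI/month; the trend component is constructed so the post-break level at
  t_j equals (1 + magnitude) times the level at t_j − 1 exactly. Raw
  streams are emitted as (NIR, Red) pairs by inverting EVI2 at Red = 0.08.
  Maximum-value compositing of noisy observations biases levels upward by
  roughly E[max of 3 draws] ≈ 0.025, which attenuates estimated magnitudes
  by a few percent — visible in the recovery numbers and left in place
  because the real compositing step has the same property.
- **Assemblages**: a per-study pool of 120 species with log-normal mean
  abundances (σ = 1, mean 8). Species occur with abundance-weighted
  occupancy (base rate 0.3 scaled by relative abundance, capped at 0.95),
  so common species form a shared compositional core among the sites of a
  study; conditional counts are shifted Poisson. Ground-truth effects are
  applied multiplicatively on this process: the richness multiplier thins
  occupancy (expected richness exactly multiplicative), the abundance/
  richness ratio rescales conditional means, the evenness shift tilts mean
  abundances toward dominance at fixed total, and the turnover fraction
  swaps present species for random absent pool members, eroding the shared
  core. Sampling extents follow method-typical footprints (30–500 m) with
  log-normal scatter; 18% of sites have the extent missing.
- **Effects**: the default per-magnitude-bin effect table injects richness
  multipliers 0.84–0.985, abundance multipliers 0.89–0.99, evenness tilts
  up to 0.3 and turnover fractions 0.05–0.35, graded by severity — echoing
  the magnitude ordering of effects reported for abrupt land change
  (grand-mean losses of a few percent, ~15% richness loss beyond a 50% EVI
  loss, strongly reduced similarity in the severest bin). Within-bin
  variance of effects is not modelled (no published value exists); the
  table is user-overridable.
- **Reproducibility**: one global seed expands to per-unit substreams via
  counter-based keys (seed, stream, unit index), so adding sites never
  perturbs existing draws, and identical (config, seed) gives byte-identical
  CSV output (checked by digest).

**What the synthetic data do not emulate**: spatial autocorrelation between
sites, multiple breaks per series, realistic satellite revisit/orbit
patterns, within-study variance of effect sizes, and recovery dynamics in
time (the effect table is keyed by magnitude bin only). Passing tests
therefore demonstrate that the pipeline recovers known effects under the
stated generative model — not that the empirical effect sizes of any real
landscape would be reproduced.

## 8. Problem sizes used in the checks

The statistical checks run at sizes chosen to keep the full suite fast
while leaving comfortable statistical margins: 500 + 500 series for
detector power and size; 100 replicates of the 40 × 30 GLMM recovery; 100
end-to-end null-calibration replicates at 6 studies × 6 sites with 132-month
series; 50 composition replicates at 10 studies × 20 sites; 200 series for
the MAD-filter characteristics. The acceptance script re-runs the same
experiments (with 40 GLMM replicates and a 12 × 16 pipeline landscape) from
a user-supplied seed.
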
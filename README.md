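# lagshift

Abrupt land change — the single largest shift in the magnitude or trend of
a site's photosynthetic activity — leaves an imprint on local biodiversity
that persists for years. `lagshift` is a tested, reusable Python pipeline
for quantifying that imprint: it detects single structural breaks in
monthly Enhanced Vegetation Index (EVI) time series, summarizes each break
by its magnitude shift, trend difference and time passed before biodiversity
sampling, and compares species richness, abundance, evenness and
compositional turnover between changed and unchanged sites with paired
hierarchical models. Because the original data sources of such analyses
(global biodiversity databases joined to satellite archives) are not
redistributable at desk scale, the package ships a first-class synthetic
landscape generator with known ground truth, so every stage is testable
end to end and parameter recovery can be demonstrated rather than assumed.

It is aimed at macroecologists and biostatisticians who want a transparent
reference implementation of this analysis chain, or a harness for studying
its operating characteristics (detector power and size, attribute recovery,
model calibration) under controlled conditions.

## The model

Each per-site monthly EVI series is fitted with a segmented harmonic-trend
regression

    ȳ_t = α_s + β_s t + Σ_{p=1}^{k} γ_p sin(2πpt/12 + δ_p) + ε_t,

with segment-specific intercept α_s and slope β_s (s ∈ {1,2}) and a shared
seasonal term of order k = 2. The single most influential break is the
RSS-minimizing candidate month, and it is reported only when an OLS-MOSUM
test on the no-break residuals rejects (α = 0.05) *and* the one-break BIC
improves on the no-break BIC. Detected breaks yield three binned
attributes: magnitude (ŷ_j − ŷ_{j−1})/|ŷ_{j−1}|, trend difference
β_after − β_before, and time passed t_n − t_j.

Site-level biodiversity measures — richness, effort-adjusted log₁₀
abundance, arcsine-square-root Hurlbert PIE, and pairwise Sørensen
similarity — are then modelled against the attribute bins with unchanged
sites (UC) as the within-study reference: a Poisson GLMM with an
observation-level random effect for richness, Gaussian mixed models for
abundance and evenness, random-effect structures selected by AIC, and
full-versus-null likelihood-ratio tests with per-bin Wald statistics.
Compositional similarity is summarized as a bin × bin matrix relative to
the UC–UC mean and clustered by complete linkage on Manhattan distances.
See `docs/methods.md` for the full account.

## Worked example

Simulate a small landscape (8 studies × 12 sites, seed 7), run every stage,
and print the effect tables:

```python
from lagshift.config import SimulationConfig
from lagshift import pipeline

cfg = SimulationConfig(n_studies=8, sites_per_study=12, seed=7)
manifest = pipeline.run_all(cfg, "demo")
print(manifest["counts"])
print(pipeline.summarize_run("demo"))
```

which prints (abridged):

```
{'sites_in': 96, 'sites_clean': 96, 'breaks_detected': 46,
 'sites_undetectable': 0, 'models_fitted': 12}

== pie ~ presence (LRT chi2=11.70, df=1, p=0.000625***; AIC=-294.3;
   random: study+block+land_use+presence_slope) ==
  changed              -1.95% (SE 0.91%) *
== richness ~ presence (LRT chi2=1.00, df=1, p=0.318; AIC=584.9;
   random: study) ==
  changed              -3.79% (SE 3.72%)
```

Reading: of 96 simulated sites, 46 carried a detected abrupt change.
Assemblages at changed sites were on average 1.95% less even (PIE) than
paired unchanged sites — significant by both the LRT against the null
model and the per-bin Wald test — while the 3.79% richness deficit is not
distinguishable from zero at this small landscape size. At the generator's
default scale (40 studies × 30 sites) the injected effects are recovered
with near-nominal coverage; see the acceptance checks below.

The same run is available from the shell:

```sh
lagshift run-all --out demo --seed 7
lagshift summarize --in demo
```

and each stage (`simulate`, `preprocess`, `detect`, `attributes`,
`diversity`, `model`, `compose`) can be run standalone on the previous
stage's CSV files. Re-running with the same config and seed reproduces
byte-identical outputs; the manifest records a SHA-256 digest per file.

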
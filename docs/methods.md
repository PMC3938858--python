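# Methods

## The study design being modelled

The pipeline implements a small-area ecological association study: one
row per reporting zone (an intermediate statistical geography of roughly
4,000 households), with a land-quality exposure summarised from point
soil geochemistry, ambient air pollution taken as known zone means, a
deprivation classification aggregated up from smaller census data zones,
and respiratory hospital admissions as the health outcome.  Associations
are screened with Pearson correlations and then modelled with log-link
GLMs of the standardised incidence ratios.  Nothing in the pipeline is
causal: it quantifies spatial association at the zone level, with all
the usual ecological-fallacy caveats.

## Point-to-zone aggregation

Samples are assigned by containment.  Rectangular (grid) zones use the
half-open convention [x0, x1) × [y0, y1), so a point on a shared edge
belongs to exactly one zone; polygon zones (GeoJSON) assign boundary
points to the lowest containing `zone_id`, and overlapping interiors are
an error.  Coordinates are planar and unit-agnostic; no CRS handling is
attempted.  Zone concentration averages are geometric means,
exp(mean(log x)) — the natural location summary for the strongly
right-skewed, approximately log-normal concentration distributions of
urban soil surveys.  Zones keep their sample count `n_samples` so users
can flag or weight sparsely sampled (typically rural) zones; nothing is
suppressed.  Values below a detection limit, when limits are supplied,
are substituted at DL/2 by default (configurable to exclusion); Cd and
Hg are outside the element set entirely because urban surveys typically
censor most Cd and do not report Hg.

## The composite soil-metal index

Three steps: (1) per metal (As, Cr, Ni, Pb, Se — the elements of concern
under UK contaminated-land guidance), class the pooled study-wide log
concentrations into deciles and score 1–10; (2) sum the five scores per
sample (bounds 5–50); (3) take the arithmetic mean of sample totals per
zone.  Scoring is rank-based, hence invariant to any strictly monotone
study-wide transform; the log transform is retained for consistency
with the rest of the log-scale processing and tie granularity.

Decile convention (chosen for exact reproducibility): the nine cut
points are the order statistics at positions floor(k·n/10), k = 1..9, of
the sorted fitted values, and a value belongs to the lowest class whose
cut point it does not exceed.  Equivalently a fitted sample's score is
ceil(10·r/n) with r its minimum rank and ties sharing the lower class.
Unlike interpolated percentile cut points, this binning is exact for
every n (classes of size ⌊n/10⌋ or ⌈n/10⌉) and identical on raw or log
values.  All-identical input is a degenerate-distribution error.
Deciles are fitted on all samples pooled (urban + rural), one CDF per
metal; samples missing any of the five metals are flagged and excluded
from zone means.

## Indirect standardisation

Standard rates default to internal standardisation: stratum rate =
study-wide cases / study-wide population per (age band, sex), expressed
per 100,000.  Expected counts are Σ pop·rate over strata, SIR = O/E.
Internal rates force ΣE = ΣO exactly, which the tests assert to 1e-9
relative.  External standard rates can be passed directly to
`compute_sir`.  Zones with E below 0.5 expected cases are flagged
`unstable` but retained.  Age bands are configuration; the default is
0–14, 15–44, 45–64, 65–74, 75+ by sex — a coarse but conventional
partition for respiratory admissions.  Smoking is not modelled;
deprivation is its customary area-level proxy.

## Health-free deprivation index

Domain rankings (1 = most deprived) are normalised to [0, 1], passed
through the exponential transform −23·ln(1 − R·(1 − e^(−100/23)))
(the published SIMD/IMD methodology; it concentrates discrimination in
the deprived tail), combined as a weighted sum and re-ranked.  Default
weights are the published 2009 scheme with the health domain removed
and the rest renormalised (income .28, employment .28, education .14,
access .09, crime .05, housing .02 before renormalisation); both the
weights and the transform are configuration, not constants of nature.
Deciles follow ceil(10·rank/n) (class sizes differ by at most one);
zone values are the median member-data-zone decile, with half-integer
medians floored toward the more-deprived class — the conservative
direction for an inequality analysis.  Note the exponential transform is
convex, so reversing every domain's ranking does *not* exactly reverse
the composite (it does under the `transform="linear"` option); this is a
property of the published methodology, not an implementation artefact.

## Association models

`critical_r(n, alpha)` is the exact closed form t_{α/2,n−2}/√(t²+n−2)
(0.117461 at n = 279, α = 0.05).  Printed textbook tables built on
coarse df grids or Fisher-scale approximations can disagree in the third
decimal; the exact value is used for all significance flags.
Correlations use listwise deletion over the selected variable set and
report the common n.  Deprivation deciles keep their native direction
(1 = most deprived), so deprivation–adversity correlations come out
negative by convention.

The GLM default is Poisson on observed counts with offset log E —
the likelihood actually generating count-derived SIRs — which models
log SIR linearly in the covariates; a Gaussian family with log link on
the SIR itself is available for comparison (`family="gaussian_log"`).
Exactly one soil covariate (composite index or one metal's zone
geometric mean) may enter a model: the metals are strongly mutually
correlated and entering several is refused, not silently fitted.  NO₂
and PM₁₀ (r ≈ 0.98) are likewise never entered together.  Deprivation
enters as indicator terms for deciles 2–10 with decile 1 as reference;
levels absent from the data are dropped and recorded on the fit object.
p-values are Wald; no multiplicity correction by default.  AIC is
2k − 2·maximised log-likelihood; `select_model` returns the minimum-AIC
converged fit, ties to the smaller model.

## The synthetic-data generator

`synth.generate_study` produces a study region whose statistical
structure matches the assumptions above, with all "truth" recorded:

- **Geometry** — n_zones (default 279) rectangular zones, each a
  (1 × 3)-cell block of 1 km² cells, tiled row-major on a near-square
  lattice; the round(0.42·n) zones nearest the lattice centre form a
  compact urban block.  With the default sampling densities (exactly 4
  samples per urban km²; one sample in a rural km² with probability
  0.5) this yields ≈1,400 urban and ≈240 rural samples — the scale of a
  real urban geochemical survey.  Real polygon zones are accepted via
  GeoJSON at the I/O layer; the analysis is geometry-agnostic once
  samples are assigned.
- **Soil chemistry** — multivariate log-normal concentrations for
  As, Cr, Cu, Ni, Pb, Se, Zn with a common pairwise log-scale
  correlation (default 0.5) and urban medians of typical urban-survey
  magnitude (e.g. Pb 118 mg/kg, As 9 mg/kg); rural locations are
  shifted down by log 3 (a ~3× urban elevation).  Potassium is drawn
  independently with a mild rural elevation, mimicking a geogenic
  control element.
- **Air** — zone NO₂ and PM₁₀ share the urban/rural mean contrast and a
  common noise component (within-stratum correlation 0.97), giving a
  pooled inter-pollutant correlation ≈0.98.
- **Deprivation** — a zone-level latent severity correlates (default
  0.6) with the standardised zone soil index; each of the five member
  data zones perturbs it, and all seven domains (health included — its
  exclusion is an analysis step) load on the data-zone latent with
  shared variance 0.6 before ranking.
- **Population and cases** — zone totals ~N(8,800, 1,500²) (truncated at
  2,000) split multinomially over ten age–sex strata with fixed shares;
  stratum admissions are Poisson with mean pop·rate/10⁵·exp(η), where
  the baseline rates rise steeply with age (450–9,000 per 100,000) and
  η = β₀ + β_index·index_z + δ_decile(z) + β_NO₂·NO₂_z is the generating
  log-linear predictor.  Defaults: β_index = 0.01, β_NO₂ = 0.01, a
  linear decile gradient of −0.06 per decile, β₀ = −0.2.  These are
  placeholders that make parameter recovery well-posed — no study
  deposits a generating model — and are always visible in config and
  `truth.json`.  The covariates driving η are computed with the same
  aggregation/index/deprivation code the analysis uses, so the fitted
  GLM estimates exactly the generating coefficients; zones that drew no
  soil sample take the study-mean index in η while their analysis
  covariate stays missing (they drop out of fits listwise).

One seed drives everything through per-component sub-streams
(SeedSequence spawn keys), so a fixed seed reproduces the study
bit-for-bit and regenerating one component never perturbs another.

What the generator does *not* emulate: spatially autocorrelated noise
fields (concentrations are exchangeable within stratum given the
covariance), measurement error in air means, migration, household
microdata, or overdispersion beyond Poisson.  Passing tests therefore
demonstrate the correctness and calibration of the *pipeline* under its
own assumptions, not the behaviour of real Glasgow-like data, where
spatial confounding and overdispersion would need CAR-type models the
package deliberately omits.

## Calibration checks and problem sizes

The acceptance suite fits the full pipeline on replicated synthetic
studies at the default 279-zone scale: 100 replicates for coefficient
recovery (the 95% Wald interval must cover the generating soil-index
coefficient in ≥90) and 1,000 null replicates for type-I error of the
soil-index test (band 3–7%; 1,000 replicates put the binomial standard
error at 0.7 points, sharp enough for a ±2-point band).  Intercept
recovery is *not* checked: internal standardisation rescales expected
counts by the case-weighted mean of exp(η), which shifts the intercept
by a known constant while leaving every other coefficient identified.

## Numerical conventions

- Geometric means require strictly positive values; empty groups are
  missing, never zero.
- Decile ties always fall to the lower (more adverse) class; composite
  deprivation ties break by row order (`rankdata` ordinal).
- GLM convergence uses statsmodels defaults (IRLS, up to 200
  iterations); non-convergence is reported on the fit object, and
  `select_model` ignores unconverged candidates.
- AIC ties within 1e-9 resolve to the model with fewer parameters.

## Known limitations

- No confidence intervals on SIRs (Byar/exact) and no spatial random
  effects; both are natural extensions.
- The exponential-transform constants and domain weights are taken from
  the published 2009 methodology and are not re-derived from indicator
  data; reproducing official scores for real data zones is out of
  scope.
- Air pollution is treated as known (no exposure-model uncertainty).
- Single-year counts only; no temporal structure.
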
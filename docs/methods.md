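# Methods

## The problem

National micronutrient surveys measure serum zinc in a clustered sample of
participants (enumeration areas → households → individuals) together with
the acute-phase proteins CRP and AGP, sampling weights, and the context of
the blood draw (time of day, fasting). Three methodological issues stand
between the raw measurements and a usable map of zinc status:

1. inflammation redistributes zinc from plasma to the liver, biasing
   measured serum zinc downward in inflamed individuals;
2. deficiency thresholds depend on age, sex, time of draw and fasting
   status, so classification must be context-specific;
3. zinc status varies spatially, and mapping it from a sparse clustered
   sample requires an explicit geostatistical model on the sphere.

`zincgeo` implements this chain — exclusion cascade, inflammation staging
and adjustment, weighted prevalence, robust variography, ordinary kriging
and exceedance-probability mapping — plus a synthetic survey generator so
the whole pipeline can be validated against known ground truth.

## Exclusion cascade

Records are dropped, in a fixed order, for: missing GPS coordinates,
missing meal/draw context (either draw time or fasting status absent),
missing CRP or AGP, missing socio-demographics, and flagged analytical
outliers. Each dropped record is attributed to the *first* matching
reason, so the per-reason counts are disjoint and, together with the
retained count, partition the input. This makes attrition reporting
reproducible and auditable.

## Inflammation staging and BRINDA adjustment

Staging uses the standard four-way classification from CRP (cutoff
5 mg L⁻¹) and AGP (cutoff 1 g L⁻¹): *none* (both at or below cutoff),
*incubation* (CRP high only), *early convalescence* (both high), *late
convalescence* (AGP high only). The cell with CRP > 5 and AGP exactly 1 is
assigned to incubation so the four stages tile the marker plane; the
no-inflammation cell keeps its ≤/≤ definition.

Adjustment is the internal-regression (BRINDA) approach: one national OLS
fit of ln Zn on ln CRP and ln AGP with intercept, over the analysis sample
itself, giving slopes β₁ and β₂. Reference values are the maximum of the
lowest decile of each log-marker over the same sample (the ⌊n/10⌋-th order
statistic, at least the first). Adjusted zinc is

    Zn_adj = exp[ ln Zn − β₁ (ln CRP − ref₁)₊ − β₂ (ln AGP − ref₂)₊ ]

where each term applies only when that marker's log value exceeds its
reference, independently per marker. Consequences preserved by design:
the adjustment is the identity when both markers sit at or below their
references; with negative slopes it can only raise zinc; and because the
decile references sit below the clinical cutoffs, some records staged as
"not inflamed" are still adjusted — a property of the method, not a bug.
Slopes are applied with their estimated signs, and no truncation is
applied to the output. Marker values at or below zero (possible below
assay detection) are replaced by half the smallest positive observed value
before logging (configurable); dropping them would change the cohort.
Residual diagnostics (Jarque–Bera, Breusch–Pagan) are attached to the fit
object for assumption checking.

## Deficiency classification and prevalence

Cutoffs (µg dL⁻¹, strict `<`; a value equal to the cutoff is not
deficient) ship as an editable CSV:

| age band | sex | draw time | fasting | cutoff |
|---|---|---|---|---|
| <10 | any | morning | no | 65 |
| <10 | any | afternoon | no | 57 |
| ≥10 | male | morning | no | 70 |
| ≥10 | female | morning | no | 66 |
| ≥10 | male | afternoon | no | 61 |
| ≥10 | female | afternoon | no | 59 |
| ≥10 | male | morning | yes | 74 |
| ≥10 | female | morning | yes | 70 |

Age exactly 10 uses the ≥10 rules; children's cutoffs ignore sex.
Combinations without a published threshold (e.g. afternoon fasting) raise
an explicit "no cutoff defined" error — never a silent default — and the
synthetic generator never produces them under its defaults.

Prevalence per stratum is the sampling-weight share of deficient records,
reported for unadjusted and adjusted zinc, with a national row; it is
invariant to rescaling all weights. Point estimates only: design-based
standard errors are out of scope. Weighted summary tables report n, the
percent share of records, and the weighted mean and weighted median (the
0.5 quantile of the weight CDF with linear interpolation, which reduces to
the ordinary median under equal weights). Rank correlations among zinc,
markers, age and diarrhea are unweighted Spearman coefficients on
pairwise-complete observations — survey weighting of correlations is
deliberately not applied, since the estimand is the within-sample
association rather than a finite-population total.

## Variography on the sphere

Spatial analysis is restricted to a single demographic group (women of
reproductive age by default, the group with the widest EA coverage) to
avoid mixing age-dependent concentration levels into the spatial signal.
Records are first averaged (unweighted) within each enumeration area, with
mean coordinates; the EA is the support unit of all spatial analysis.
Marginal outliers among EA means are screened by Tukey outer fences
(Q1 − 3·IQR, Q3 + 3·IQR; quartiles by linear interpolation) and withheld
from variogram estimation only — they are reinstated for kriging, since an
extreme but genuine value should inform local prediction even though it
would inflate semivariance estimates.

Because the survey spans a subcontinental window, no single planar
projection is adequate; lags are great-circle distances on a spherical
Earth (radius 6371.0088 km, haversine formula), and directional sectors
use final bearings. On the sphere the exponential semivariance

    γ(h) = c0 + c1 (1 − exp(−h/a)),  h > 0

remains positive-definite, which is why it is the only model family
offered: c0 is the nugget (analytical error plus variation below the
sampling resolution), c1 the spatially correlated variance, and a the
distance parameter, with correlation effectively exhausted at 3a.

Three empirical estimators are provided per lag bin (default 10-km
half-open bins to 200 km; pairs beyond the last edge are discarded):
Matheron's classical mean-of-squares, and the robust Cressie–Hawkins
(fourth power of the mean root absolute difference, bias-corrected by
2(0.457 + 0.494/N)) and Dowd (2.198·median(|d|)²/2) estimators, which
resist spatial outliers. The directional variant folds bearings modulo
180° into four 45° sectors centred on 0/45/90/135° and is intended for a
visual anisotropy check, not a formal test.

Model fitting minimises Σ N_j [γ̂_j − γ(h_j)]²/γ(h_j)² (Cressie's weights,
iteratively reweighted; plain-N weighting available) with a bounded
quasi-Newton search on (c0, c1, ln a), multistarted over
a ∈ {5, 10, 20, 40, 80} km, ties broken by objective then by smaller a.
A fit that is flat over the observed lags (vanishing partial sill, or a
distance parameter shorter than the first bin) is collapsed canonically to
a pure-nugget model with a warning.

## Ordinary kriging, validation and mapping

Kriging solves the bordered semivariance system with the unbiasedness
constraint (weights sum to one); the prediction is Σλᵢzᵢ and the kriging
variance Σλᵢγ(h_i0) + ψ. The exact-interpolation convention γ(0) = 0 is
used: a prediction at a data location returns the datum with zero
variance, which also makes leave-one-out cross-validation well posed.
Kriging is global by default (a few hundred EAs is tractable); a
nearest-k neighbourhood is available for larger inputs. Duplicate data
locations are an error, never silently jittered.

Validity is screened by leave-one-out cross-validation: each EA mean is
removed and predicted from the rest, and its squared error is divided by
the kriging variance. Under a correct model these standardized squared
errors are approximately χ²₁, whose median is 0.455; the model is accepted
when the observed median falls in the published interval (0.355, 0.575),
taken as a fixed criterion rather than recomputed per n. Selection
follows efficiency: the Matheron-based fit is accepted outright when
valid; otherwise the robust-estimator fits are cross-validated and the
median-SSPE closest to 0.455 wins, with an explicit invalid flag when
nothing qualifies.

Grid prediction runs on a regular lon/lat grid (default 0.25° in the
pipeline, capped at 10⁶ nodes; a 60-m national grid is far beyond desk
scale). The probability that zinc falls below a policy threshold (default
70 µg dL⁻¹) is computed from the Gaussian prediction distribution,
Φ((t − Ẑ)/σ_K), resolving σ_K = 0 by direct comparison, and labelled with
the IPCC calibrated-likelihood phrases (virtually certain ≥ 0.99, very
likely ≥ 0.90, likely ≥ 0.66, about as likely as not ≥ 0.33, unlikely
≥ 0.10, very unlikely ≥ 0.01, exceptionally unlikely below), bins
half-open from below.

## The synthetic generator

`SimulationConfig` defaults emulate a national survey of this design: 343
enumeration areas uniform over an Ethiopia-like window (33–48°E,
3.5–14.5°N), 9–11 participants each (~3 400 records), four demographic
groups in shares YC 0.17 / SAC 0.31 / MEN 0.13 / WRA 0.39 with
group-appropriate ages and sexes. The latent EA zinc field is Gaussian
with mean 57.7 µg dL⁻¹ and exponential semivariance (c0 = 27.0,
c1 = 39.62 (µg dL⁻¹)², a = 14.79 km); the smooth component lives on EA
centroids and the nugget is realised as independent noise, matching the
kriging convention that the nugget is measurement plus micro-scale error.
CRP and AGP are log-normal — (meanlog, sdlog) = (−0.109, 1.40) mg L⁻¹ and
(−0.262, 0.45) g L⁻¹, putting ~11% of CRP above 5 mg L⁻¹ and ~28% of AGP
above 1 g L⁻¹ — coupled by a Gaussian copula with rank correlation 0.40.
Participant ln-zinc adds β_CRP (ln CRP − meanlog) + β_AGP (ln AGP −
meanlog) plus within-EA noise (sdlog 0.10, a quantity surveys rarely
report and therefore a config knob). The default slopes (−0.005, −0.05)
are sized so measured zinc carries weak rank correlations with the markers
(≈ −0.09 with CRP, −0.14 with AGP), the magnitudes typical of population
surveys; stronger slopes are used in tests that exercise slope recovery.
Missingness defaults (GPS 3.0%, meal context 5.1%, each marker 0.5%,
socio-demographics 0.12%, plus two flagged analytical outliers) reproduce
a realistic attrition cascade. All randomness flows from one mandatory
seed; a fixed seed gives byte-identical outputs.

What the generator does **not** emulate: probability-proportional-to-size
EA selection and the resulting clustered, population-weighted geography
(EAs are uniform in the window); real administrative boundaries (regions
are labels assigned at random); any dependence of inflammation or weights
on location or group; assay drift or detection-limit censoring. Passing
tests therefore demonstrate that the estimators recover the generating
process under a clean clustered design — not that any particular national
estimate is correct.

## Problem sizes and numerical choices in the test suite

Monte-Carlo studies run on a 4°×4° window (~440 km square): with ~300
uniform sites this populates the sub-45-km lag bins that identify the
distance parameter, whereas uniform sites over the full national window
leave those bins nearly empty and the range unidentifiable — a geometry
choice, documented here, that mirrors how variogram studies concentrate
sites at informative spacings. Calibration of the cross-validation SSPE
uses 300-site fields (50 replicates in the acceptance script, 150 in the
test suite, where the replicate 2.5/97.5 percentiles are also compared to
the published interval). End-to-end parameter recovery uses 315 sites and
30 replicates, asserting the median recovered distance parameter within a
factor of two and the median total sill within 25% — tolerances that
reflect the sampling noise of variogram estimation at a few hundred
sites. Covariance factorisations add a 1e-10 relative diagonal jitter for
Cholesky stability; kriging systems are solved by LU (many-target path
factorises once); negative kriging variances within numerical tolerance
are clamped to zero.

## Known limitations

- Single national BRINDA fit: no group-specific slopes, no external
  meta-analytic coefficients.
- No design-based variance estimation for prevalence or summaries.
- Exponential variogram only (the family authorized on the sphere);
  no Matérn/spherical alternatives, no REML estimation.
- Global kriging scales cubically; use the nearest-k neighbourhood beyond
  a few thousand sites.
- The validity interval (0.355, 0.575) is a fixed published criterion;
  an order-statistic interval for other n is not derived here.
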
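# Methods

This note documents the statistical procedure `rhiscov` implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Setting and notation

District health offices report monthly counts of services delivered —
first antenatal contact (ANC1), institutional delivery, and the BCG, DPT1
and DPT3 vaccine doses — through three reporting forms (ANC, delivery,
immunization). Coverage of an indicator is 100 × numerator / denominator,
where the numerator is the annual count adjusted for incomplete reporting
and the denominator is the estimated population in need. The analysis unit
is the district-year (default analysis year 2016, observed within a
2014–2018 series); national figures pool district sums.

## Data-quality scorecard

Four checks, each expressed as a 0–100 score (higher = better), averaged
into a composite:

* **Completeness** — the unweighted mean of the three form completeness
  percentages. The national value averages districts per form first
  (unweighted; weighting by expected reports would need facility counts the
  inputs do not carry). The conventional minimum acceptable rate, 80%, is
  kept in the configuration for reporting, not enforcement.
* **Outliers** — monthly values of ANC1 and DPT3 within the analysis year
  are scored with the modified Z statistic z = (x − median)/MAD, where MAD
  is the median absolute deviation; |z| > 3.5 flags an outlier. The plain
  ratio is used, *without* the 0.6745 normal-consistency constant; a
  configuration flag (`mad_scaling_constant`) restores the textbook scaling
  for users who want it. The scorecard stores 100 − (mean % of flagged
  months over the two indicators) so that all four components share a
  good-is-high orientation; the raw outlier percentage is emitted alongside.
* **Consistency over time** — the modified Z of the analysis year's annual
  total (ANC1 and DPT1) against the annual totals of all available years,
  mapped through fixed bins: |z| < 0.25 → 100, < 0.5 → 80, < 0.75 → 60,
  < 1 → 50, < 1.25 → 40, < 1.5 → 30, < 1.75 → 20, < 2 → 10, ≥ 2 → 0. The
  target year itself is included in the median/MAD set by default: with
  only three or four comparison years, excluding it degenerates the MAD too
  often; `time_consistency_include_target` overrides this. At least three
  comparison years besides the target are required.
* **Consistency between indicators** — for the pairs ANC1:DPT1 and
  DPT1:DPT3, the reported annual-total ratio is compared with the
  survey-expected ratio; the absolute difference, expressed as a percentage
  *of the expected ratio* (the bins are percentage bands around the
  expectation, which fixes the base the score definition leaves open), maps
  through ≤ 5 → 100, < 15 → 75, < 20 → 50, < 25 → 25, ≥ 25 → 0. The
  district check reuses the national expected ratio, since surveys rarely
  provide district-level ratios.

Degenerate series (MAD = 0) score z = 0 everywhere: a constant series
carries no internal evidence of anomaly. Missing months are excluded from
both the numerator and the denominator of the outlier percentage rather
than imputed as zero, which would masquerade as low outliers. The national
scorecard row is computed from pooled national counts;
`national_score_as_district_mean` provides the alternative (mean of
district rows) for comparison.

## Adjustment for incomplete reporting

N_adj = N_rep · (1 + k(1/c − 1)) with completeness c per (district, year,
form) and k ∈ [0, 1] per form, default 0.25 everywhere — the conventional
assumption that non-reporting facilities operate at a quarter of the level
of reporting ones. k = 0 is the identity; k = 1 inflates fully to N_rep/c.
The adjustment is applied to annual district totals with the annual form
completeness. Because the formula is linear in the count, adjusting each
month and summing gives the identical annual result whenever completeness
is annual, so no separate monthly mode exists. National adjusted counts are
sums of district adjusted counts (preserving additivity), and adjusted
counts remain real numbers throughout — rounding happens only at CSV
output (one decimal on percent-scale columns).

## Denominators

The demographic chain runs

pregnancies −(1 − early fetal loss)→ deliveries −×(1 + multiple births)→
total births −×(1 − stillbirth rate)→ live births −×(1 − NMR)→ surviving
infants,

with each relation exactly invertible, so the chain can be entered at any
anchor. The conventions — stillbirths as a share of total births, multiple
births as excess births per delivery, early fetal loss as a share of
pregnancies — are the usual denominator-guidance readings of these rates;
each direction can be flipped in `ChainConventions` if a data source
defines a rate the other way.

The five methods anchor the chain at: projected population × CBR/1000
(census 1), projected live births (census 2), or an adjusted service count
inflated for non-use, N_adj/(1 − nonuse), at pregnancies (ANC1), live
births (BCG — given at birth to live newborns) or surviving infants (DPT1 —
given at 6 weeks, so the cohort has passed the neonatal period). DPT3's
target population is surviving infants (set nmr = 0 to use uncorrected live
births). Non-use proportions are national survey scalars applied to all
districts unless district values are supplied. The method anchored on the
indicator being measured is excluded from that indicator's coverage.

Target populations per indicator: ANC1 → pregnancies, delivery →
deliveries, DPT3 → surviving infants.

## Agreement classification

An estimate is CONSISTENT when ci_low ≤ coverage ≤ ci_high — a closed
interval, the natural reading of "within the CI"; endpoint hits count as
agreement. Comparison uses the unrounded coverage by default; a
`compare_rounded` mode compares the one-decimal value instead, matching
printed tables. The gap is coverage − survey point in percentage points,
and its sign gives OVER/UNDER outside the CI. A per-year national coverage
table (`coverage_trend`) is emitted descriptively; no trend statistics are
computed. Survey CIs are taken as given; no formal test of the RHIS–survey
difference is attempted beyond CI membership.

## Synthetic data generator

The generator emulates a 14-district country over 2014–2018 with the 2015
census district populations (total 7,092,113) and annual growth rates
spanning 1.8–8.5%. Per district-year it derives true live births from the
CBR (34/1000), the full chain from the demographic truth (stillbirth rate
0.024, multiple-birth proportion 0.015, early fetal loss 0.04, NMR 0.031),
true service counts as target × true coverage, a fixed 12-month
multiplicative seasonality profile (mean 1), and reported counts as
true/(1 + k_true(1/c − 1)) — the exact inverse of the adjustment, which is
the model-consistent way to withhold services from non-reporting
facilities. Non-use is the definitional complement of anchor coverage
(1 − coverage/100), which is what makes all five denominator methods agree
on the truth. Distortions layer on top: lognormal monthly noise
(mean-one, σ configurable), outlier months multiplied by a stated factor at
a stated rate, survey points perturbed by normal noise with CI = point ±
1.96·SE (truncated to [0, 100]), numerator over-reporting factors, census
projection biases, and cross-district care-seeking shifts of numerator
counts. A single `noise_scale` dial multiplies σ, the outlier rate and the
survey SEs. Fixed seeds give byte-identical CSVs.

Presets:

* `clean` — complete reporting, zero noise, district-level non-use, survey
  SE 0 with a fixed 0.5 pp CI half-width (a zero-width interval is
  degenerate under floating-point recovery, so a small reporting precision
  is assumed a priori). Under this preset the pipeline recovers true
  coverage to ~1e-13 pp for every indicator, district and method.
* `sierra_leone_like` — form completeness averaging 94% (ANC), 89%
  (immunization) and 94% (delivery) across districts, with the Western
  Area districts carrying the low rates (immunization 69.1%, delivery 83.8
  and 86.6%); k = 0.25; national non-use scalars; national true coverages
  97.1% (ANC1), 76.2% (delivery), 84.9% (DPT3), and — since survey values
  for the anchor-only services are not published — 95% (BCG) and 93%
  (DPT1), realistic for the setting; monthly σ = 0.05; outlier rate 0.005
  at 2.5×; district survey SEs 1.4/2.2/2.2 pp and national SEs
  0.33/1.12/1.0 pp for ANC1/delivery/DPT3.
* `degraded` — the over-100% failure mode: ANC1 over-reported by 30% in
  five districts, census projections biased ×0.85 in half the districts
  and ×1.15 in the other half, so district census-based coverages blow
  past 100% while the pooled national figure, where the biases offset,
  moves far less.

Noise propagation under `sierra_leone_like` was sized analytically: annual
relative SD per indicator ≈ √(σ²/12 + rate·(magnitude−1)²/12) ≈ 3.4%, so
the DPT3/DPT1 coverage ratio has SD ≈ 4.8% (≈ 4 pp at 85% coverage) and the
expected district mean absolute error ≈ 3–3.5 pp including the ~1 pp bias
from national non-use scalars — below the 4.3 pp survey sampling
uncertainty (1.96 × district SE) used as the recovery bound in the test
suite. The replicate experiments use 20 seeds per noise scale; the whole
suite and the acceptance script each run in well under a minute.

**What passing these experiments does not show.** The generator's noise is
multiplicative, independent across months and indicators; real reporting
errors are correlated (stock-outs, campaigns, retrospective data entry),
survey CIs are design-based rather than symmetric normal, completeness is
itself measured with error, counts are integers, and population
projections err systematically rather than by a clean multiplicative bias.
Exact recovery demonstrates internal consistency of the pipeline algebra,
not accuracy on real extracts.

## Numerical conventions

* All internal arithmetic in float64; no intermediate rounding. CSV output
  rounds percent-scale columns to one decimal.
* MAD = 0 ⇒ all z = 0 (no outliers flaggable).
* Score-bin boundaries follow their printed inequalities exactly
  (0.25 → 80, 2 → 0; 5 → 100, 15 → 50, 25 → 0); both mappings are total
  and monotone non-increasing.
* Chain ordering (pregnancies ≥ deliveries; total ≥ live ≥ surviving
  infants) is validated with 1e-9 relative slack for round-off.
* District labels are free strings matched exactly (case-sensitive) across
  files, with a cross-file consistency check at load time; completeness
  files carry an explicit unit column (`fraction`/`percent`) and values
  above 1 without one are rejected, preventing silent 100× errors.

## Known limitations

* Form-level (not indicator-level) completeness; per-form district values
  are required, as exported by aggregate platforms.
* k is a single national constant per form; facility-category- or
  district-specific k is out of scope.
* The indicator set is fixed to the five listed; the analysis is fixed to
  14 districts as supplied (no handling of district splits mid-series).
* No survey microdata handling: benchmark points, CIs and expected ratios
  are inputs.
* No mapping/choropleth output; results are tabular CSVs.
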
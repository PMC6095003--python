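# Methods

## Volumetry

Tissue-class images hold per-voxel fractions in [0, 1]; a tissue volume is
the sum of fractions times the voxel volume, converted mm³→ml (factor
1/1000) and reported at full precision. Probabilistic maps are summed
directly rather than binarized first, so partial-volume voxels contribute
fractionally. Regional volumes multiply the tissue maps with pre-aligned
binary atlas masks and apply a fixed per-region tissue rule: thalamus and
putamen GM+WM, caudate GM only, corpus callosum WM only. BP (brain
parenchyma) is GM+WM.

All grids must share shape and voxel size; no resampling or registration is
performed — masks are assumed already in the image space. Segmentation,
lesion delineation and atlas registration are out of scope; the package
starts from their outputs.

TIV is computed as the GM+WM+CSF sum and flagged as a tissue-sum surrogate
in output metadata (`tiv_method`). The downstream adjustment only needs a
consistent head-size covariate, so any monotone, subject-stable TIV
estimate serves; swapping in an external TIV column is supported by simply
providing it in the cohort CSV.

Lesion filling estimates healthy-WM intensity as the mean T1 intensity over
voxels with WM fraction above a threshold (default 0.9) and outside the
lesion mask, then replaces lesion voxels with that mean, optionally adding
Gaussian noise at the estimated healthy-WM SD. With noise disabled the
operation is idempotent. If no healthy-WM voxel exists the operation
refuses rather than guessing.

## Normative adjustment

Adjustment is sequential, TIV first and then age, never joint:

* **TIV stage** — per-region OLS of raw volume on TIV over the reference
  cohort (≥ 3 subjects, non-degenerate TIV variance required). Residuals
  have exactly zero mean on the reference cohort.
* **Age stage** — a cubic smoothing spline of the TIV-adjusted volume on
  age, with the penalty chosen by generalized cross-validation
  (`scipy.interpolate.make_smoothing_spline`); a fixed penalty can be
  supplied instead (`lam`). Duplicate ages are collapsed to weighted means
  because the spline routine needs strictly increasing abscissae. The fit
  requires ≥ 10 subjects spanning ≥ 20 years. Outside the reference age
  range the trajectory is clamped to the boundary value and an
  `age_extrapolated` flag is raised rather than extrapolating a cubic.

Adjusted volumes live on a residual scale (reference mean ≈ 0). They are
deliberately not re-centered to raw-volume means: the z-score only needs
relative position, and re-centering would add a constant that cancels in
the standardization anyway.

Control moments are computed per scanner and per region from the adjusted
volumes of the scanner-control cohorts (≥ 2 controls per scanner; the SD
uses the n−1 denominator — at the cohort sizes involved, ≥ 34, the
difference from the n denominator is far below one z-score unit of
precision). When no separate scanner-control table is given, the reference
cohort doubles as the control cohort and the model provenance flags this
(`controls_are_reference`). The whole model — regression coefficients,
spline knots/coefficients, moments, provenance — serializes to JSON and
reloads to a model whose outputs are bit-identical.

No sex adjustment is performed; the adjustment chain is defined solely over
TIV and age.

## Z-scoring and grouping

z = (adjusted volume − control mean) / control SD, with the moments taken
from the subject's own scanner. Scanner controls therefore self-normalize
to exactly mean 0, SD 1 per region, and pooled two-scanner cohorts are
approximately standard normal. Missing regions propagate as NaN with a
flag; an unknown scanner is an error, since silently borrowing another
scanner's moments would defeat the stratification.

Grouping applies a fixed cut-off (default −1.96, the 2.5% lower tail) to a
configurable region pair, default (thalamus, BP). Equality with the cut-off
counts as atrophic (≤); this convention is configurable and measure-zero
for continuous data. BP-atrophy-without-thalamic-atrophy is a first-class
`bp_only_outlier` label: such subjects are listed in the summary and
excluded from the group-level statistics rather than treated as errors.
The region pair can be swapped (e.g. corpus callosum for thalamus) to run
the same staging on other subcortical structures.

## Statistics

* Quantiles use linear interpolation (the "type 7" rule); medians of
  ordinal variables (EDSS half steps, gridded SDMT) therefore stay on or
  halfway between grid points, matching how such scores are reported.
* Wilcoxon rank sum: exact null distribution when both samples have ≤ 8
  observations and no ties; exhaustive permutation when that small but
  tied; otherwise the tie-corrected normal approximation *without*
  continuity correction, which makes the two-group case agree exactly with
  Kruskal–Wallis.
* One-way ANOVA with Bonferroni-multiplied pairwise t post-hocs (capped at
  1); one-sample t for regional z against zero.
* Kruskal–Wallis with midrank tie correction; an all-tied input is flagged
  and reported as H = 0, p = 1 instead of erroring.
* Dunn's pooled-rank pairwise z with tie term Σ(t³−t)/(12(N−1)), adjusted
  by Šidák: p_adj = 1 − (1 − p)^m over the m = k(k−1)/2 pairs. Every
  adjusted p is annotated with its family size m.
* All tests are two-sided; significance is flagged at α = 0.05 by default.

`build_report` assembles a phenotype-comparison table (median (q1; q3) per
variable, Wilcoxon RRMS vs SPMS), per-region one-sample t and across-region
ANOVA of the z-scores, and per-phenotype Kruskal–Wallis across the three
atrophy groups with Dunn–Šidák post-hocs where the omnibus test is
significant.

## Synthetic cohorts

The generator defines the ground truth the analysis is tested against.
Per region, volumes follow

    v = baseline + slope·(TIV − TIV₀) + a₁·(age − 45) + a₂·(age − 45)² + ε,

with homoscedastic Gaussian ε — the simplest model consistent with the
normality assumption behind the −1.96 cut-off — and a monotone-decreasing
linear-plus-quadratic age trend over the 20–70 y default range. Baselines
and residual SDs sit at adult-brain scale (GM 650 ml, WM 520 ml, thalamus
15.5 ml, ...). TIV is N(1500, 130²) ml; ages are uniform. Cohort sizes
default to the study conditions: 316 reference controls, 50 + 34 scanner
controls on two systems, 128 RRMS + 57 SPMS patients.

Scanner effects are affine (scale·v + offset per scanner; default a mild 2%
scale difference between systems). Patient atrophy is applied per hidden
ground-truth group as (thalamus, BP) shifts in control-SD units — so the
expected downstream z equals the configured shift — with the BP shift split
equally between GM and WM so that bp = gm + wm moves coherently. Default
group frequencies per phenotype and the per-group clinical-score links
(EDSS on the half-step grid, SDMT on a quarter-point grid, log-normal
lesion load and disease duration with group/phenotype-dependent medians)
are set to the observed cohort structure of the study this pipeline
operationalizes; the published source provides only medians and IQRs, so
the distributional forms are modelling assumptions, not reproductions.

What the generator does *not* emulate: realistic MRI appearance (bias
fields, partial-volume texture), region–region correlations beyond the
shared TIV/age dependence, sex effects, and longitudinal change. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under its own assumptions, not segmentation robustness on
real scans.

The voxel phantom is a nested-ellipsoid head (CSF shell, GM shell, WM
core, named subcortical ellipsoids, spherical WM lesions) on a small grid.
Its ground-truth volumes are computed by voxel counting on the generated
maps — never from the analytic ellipsoid formula — so the volumetry stage
can be checked bit-exactly.

All randomness flows from a single integer seed, split into independent
sub-streams per generator, so identical configurations reproduce outputs
bit-identically.

## Numerical choices and problem sizes

* OLS via `numpy.polyfit`; spline penalty by GCV. A constant shift of all
  TIVs is absorbed by the refit up to GCV's sensitivity to last-ulp
  residual changes (observed z differences ≲ 1e−4).
* Cohort CSVs are written with shortest round-trip float text and read with
  exact float parsing, so write→read is value-exact.
* Simulation-based checks run at sizes chosen to make their tolerances
  sharp but cheap: moment/offset recovery at n = 10,000, tail calibration
  at n = 10,000 healthy subjects (3 binomial-SE band around 2.5%), type-I
  error of each test over 2,000 null replicates at n = 12 per group
  (accepted band 0.03–0.07 at α = 0.05), and exhaustive rank-test
  enumeration up to total n = 8.

## Known limitations

* The TIV surrogate is a tissue sum, not a skull-based estimate; absolute
  TIV values are not comparable to external tools, only consistent within
  the pipeline.
* The age trajectory is a generic smoothing spline; with very small or
  age-clustered reference cohorts the GCV penalty can under-smooth, which
  is why the fit enforces a minimum n and age span.
* Group statistics treat subjects as independent; repeated scans of one
  subject are not modelled.
* The published cohort-level result tables depend on unpublished
  patient-level data and are not reproduction targets; the synthetic
  cohorts match them in structure, not in numbers.
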
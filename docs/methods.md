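# Methods

## Model

The quantity of interest is the normalized sensitivity of a condition's
prevalence to a body-composition biomarker,

    N_CB = sigma_B * dP_C/dB,

the percentage-point change in prevalence per population standard
deviation of the biomarker.  Prevalence is used as a cross-sectional proxy
for risk; the score is associational, not causal.  The estimator assumes
prevalence is approximately linear in the biomarker over the populated
range — the same assumption that justifies summarizing a map by a single
slope.  All prevalences are handled in percentage points (0–100), so NORSE
magnitudes land on the scale familiar from survey analyses (single digits
to a few tens).

## Biomarker registry

23 indices are built in, grouped as regional (WHR, WThR, ABSI, RFM, WeThR,
WHtR, BAI, percent trunk fat, waist, hip), global (PBF, fat-to-lean ratio,
FMI, ponderal index, BMI, weight, FFMI) and weakly composition-related
(upper-arm length, bicep, calf, thigh, height, leg length).  Formulas are
the standard published ones (BMI = kg/m²; ABSI = waist_m / (BMI^(2/3) ·
height_m^(1/2)); RFM = 64 − 20·height/waist + 12·[female]; BAI =
hip_cm/height_m^1.5 − 18; and so on), with all lengths ingested in cm and
masses in kg; formulas convert to SI internally.  Percent trunk fat
defaults to trunk fat over body weight, switchable to trunk over total
fat.  Every formula is a registry entry and can be overridden or extended,
so alternative published variants can be swapped in without touching the
estimators.  The registry serializes to a YAML-able config (builtin /
passthrough / ratio formula ids).

Population moments (mu, sigma) are computed per analysis population —
per sex, after filters — with the population SD convention (ddof = 0,
configurable; immaterial at survey sample sizes).  Values derived from a
row missing any required field are missing; non-positive raw measurements
are treated as recording errors and set missing with a warning.

## Maps

Grids have cell side sigma/2 with edges at mu + k·sigma/2 (k integer):
deterministic, and equivariant under affine unit changes so cell
memberships never depend on units.  Bins are half-open [left, right) with
the topmost edge closed.  Maps are complete-case on their axes and (for
p-maps) the condition; the suppression denominator n_tot counts exactly
those rows.  Cells with n_cell < 40 or below 0.2% of n_tot are flagged
suppressed — the mask hides cells from estimation and display but never
deletes counts.  The same rule is applied to d-maps (configurable), since
tiny cells are noise in either view.

## Estimators

**1D.** S_CB is the count-weighted least-squares slope of per-cell
prevalence on the geometric cell center over non-suppressed cells (at
least two required); N_CB = sigma_B · S_CB exactly.  The closed-form
weighted slope is exact on linear inputs.  Alternative abscissae exist in
the fit diagnostics, but the center convention is the default; with
sigma/2 cells the center-vs-cell-mean discrepancy biases the slope by
roughly 2% at survey sample sizes.

**2D.**  Per-row scores (along x, holding the y bin fixed) and per-column
scores (along y) are the same weighted slopes applied to 1D slices; these
are the blue/brown numbers annotated at row and column ends of a rendered
p-map, with |N| < 2 hidden as annotation noise (display only — aggregation
always uses every usable line).  For the aggregated x/y scores two
strategies are provided:

* `gradient` (default): a count-weighted plane fit of per-cell prevalence
  on per-cell **mean** coordinates.  Under a linear risk model a cell's
  prevalence is exactly linear in its mean z-scores, so this estimates the
  prevalence gradient consistently.  It matters on strongly correlated
  axes: within one waist row, weight still varies and co-varies with
  waist, so averaging row slopes attenuates the along-x score (about 25%
  at waist–weight r ≈ 0.9), while the joint fit recovers the generating
  coefficients to within sampling noise.
* `rowmean`: the count-weighted (or plain) mean of per-row / per-column
  scores, matching the annotated numbers exactly.

NORSE separation is y_norse − x_norse.  In pair rankings each pair is
oriented once — the member with the larger overall mean score becomes the
y axis — so separations are positive for fat-vs-lean pairs and identical
in orientation across sexes and conditions.

**Rankings.** Per-sex averages are the arithmetic mean of the six
per-condition scores; the cross-sex ranking key is the mean of the two
per-sex averages, computed at full precision.  Display rounding is half
away from zero to one decimal (7.65 → 7.7), applied only at output; the
rounder snaps at nine decimals first so that sums whose float
representation sits one ulp below an exact half still round as printed
arithmetic does.

**Age stratification.** Decade brackets 20–80 plus 80+ by default
(configurable); brackets are [lo, hi) with the last closed.  Moments,
grids and maps are recomputed within each stratum, consistent with the
per-analysis-population convention.  A bracket without enough usable cells
yields an unavailable result (NaN) rather than an exception, so curves
with sparse tails still plot.

## Synthetic cohorts

The generator emulates the structure the estimators assume, not any real
survey's moments.  Anthropometrics are log-normal around sex-specific
typical values with correlation induced by a single latent size/adiposity
factor (corr(i,j) = lambda_i·lambda_j, guaranteeing a valid covariance);
default loadings give waist–weight r ≈ 0.90 and waist–hip r ≈ 0.86, which
produce realistic 2D maps with both signs of sensitivity.  Trunk fat is a
bounded share (≈ 0.28–0.52) of total fat.  Age is uniform on 20–80 by
default.  Condition flags are Bernoulli draws from per-participant
prevalence, linear (clipped to [0, 100]; defaults keep clipped mass well
under 1%) or logistic in the z-scores of named registry biomarkers, with
optional concave age modulation of the slopes.  For the linear link the
ground-truth NORSE of a modelled biomarker is its coefficient exactly; for
the logistic link it is the population-mean derivative, evaluated by Monte
Carlo with a seed derived from the config's.

What the generator does **not** emulate: survey design weights and
clustering, measurement error, informative missingness (holes are MCAR),
secular cohort trends, and comorbidity correlation beyond shared biomarker
dependence.  Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not agreement with any real survey's
published coefficients.

## Numerical notes

* Affine invariance of NORSE is exact in floating point for power-of-two
  rescalings (every intermediate scales exactly); for arbitrary unit
  changes (cm → m) results agree to ~1e-9 relative, limited by rounding of
  the transformed inputs.
* Replacing B by −B mirrors bins and flips the score's sign; with
  continuous data (no values on bin edges) the flip is exact to float
  precision.
* The weighted-slope denominator vanishing (all usable cells in one
  column of centers) raises an insufficient-support error, as does any
  slice with fewer than two usable cells.
* Problem sizes in the test-suite recovery checks — 2×10⁵ participants
  per sex for coefficient recovery, 10⁵ per sex for the age-curve shape —
  put binomial noise on estimated scores well inside the asserted
  tolerances while keeping the whole suite fast.

## Known limitations

* Cross-sectional associations only; self-reported condition flags.
* The SAS-transport (XPT) ingest path reuses the CSV mapping machinery via
  pandas' xport reader but has no bundled binary fixture, so it is
  exercised only through the CSV route in tests.
* A few indices (WeThR, PTF, FTL, BAI) have more than one published
  variant; the built-ins follow the standard literature definitions, and
  the registry override mechanism exists precisely so a user can
  substitute a preferred variant.
* Ranking is implemented for 1D and 2D models; the gradient machinery
  generalizes, but higher dimensions thin the cells rapidly (curse of
  dimensionality) and are out of scope.
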
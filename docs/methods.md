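# Methods

`grainspec` implements the complete chemometric workflow used to build
near-infrared reflectance (NIRS) prediction models for brown-rice flour
composition: diversity-driven sample selection from spectra, scatter
correction and derivative preprocessing, PLS-family calibration with
cross-validated factor choice and outlier elimination, and the external
validation statistics by which such models are judged.  Because germplasm
scan sets are rarely redistributable, the package also ships a synthetic
generator that reproduces the statistical structure of such a study, so the
whole pipeline runs and is tested end to end without any external data.

## Data model

Spectra are apparent absorbance, Log(1/R), on a shared strictly increasing
wavelength grid; the default grid is 400–2,490 nm at 2 nm steps (1,046
points), the range of a scanning monochromator instrument.  Reference values
are percent dry basis for five traits: total protein, total dietary fibre
(TDF), total starch, amylose and oil.  Protein is tied to Kjeldahl nitrogen
by protein = %N × 5.95, the nitrogen-to-protein factor for rice.

## Synthetic study set

The generator emulates a ~500-accession landrace collection:

* **Trait marginals.** Each of protein, TDF, starch and oil is drawn from a
  70/30 mixture of a range-scaled Beta(2, 2) and a uniform over the full
  range.  The Beta hump mimics the biological bulk; the uniform component
  guarantees mass at the extremes, the situation a germplasm screen is
  designed for.  Default ranges (% dry basis): protein 6.45–14.63, TDF
  4.43–5.84, starch 65–85.45, amylose 5.23–30.7, oil 3.05–7.00.
* **Amylose** is a physical sub-fraction of starch, so it is generated as a
  uniform fraction (0.07–0.41) of each sample's starch, clipped to its own
  range; amylose ≤ starch holds row-wise by construction.
* **Spectra.** Beer–Lambert-style linear mixing of Gaussian constituent
  bands placed at the six absorption features of brown-rice flour: 1,196 and
  2,322 nm (C–H, oil), 1,466 nm (N–H protein with a broad O–H starch
  shoulder and a narrow fibre component), 1,634 nm (O–H water), 1,904 nm
  (O–H/C–O starch) and 2,288 nm (N–H protein with a broad amylose
  shoulder).  Band widths (σ 10–40 nm, i.e. FWHM ≈ 25–95 nm) and unit
  absorptivities are free parameters chosen so that the six constituent
  signatures are linearly independent and the mean spectrum keeps a local
  maximum at each centre.  Water (moisture, uniform 9.5–11.9 %) is a nuisance
  constituent, never a predicted trait.
* **Baseline and scatter.** A smooth instrument baseline rises ≈0.5 AU
  across the grid (offset 0.2, slope 2 × 10⁻⁴ AU/nm, mild curvature),
  matching the strong upward slope of real flour Log(1/R) spectra.  The
  slope is not cosmetic: multiplicative scatter correction divides by a
  per-sample fitted slope, and when the shared baseline dominates that fit
  the correction stays essentially linear in composition (with scatter and
  noise off, MSC followed by a 6-factor PLS reproduces every trait with
  RSQ > 0.999).  Per-sample scatter is multiplicative slope ~ N(1, 0.05²)
  and additive offset ~ N(0, 0.02²) — exactly the artefacts MSC and SNV-DT
  are designed to remove — plus i.i.d. noise of SD 3 × 10⁻⁴ AU, the order of
  a 32-scan-averaged instrument.
* **Determinism.** One seed drives composition and spectral noise streams
  (the latter through a spawned sub-seed); identical config + seed gives
  byte-identical serialised output.

What the generator does **not** emulate: real rice NIR band shapes beyond
placement, wavelength-dependent noise, instrument drift, temperature and
moisture interactions, or any nonlinearity of diffuse reflectance.  Passing
tests therefore demonstrate that the algorithms are correct and the workflow
is coherent on data with the assumed structure — not that the same numeric
performance would be reached on real scans.

## Preprocessing

* **MSC.** Each spectrum x is regressed on a reference spectrum m (the
  calibration-set column mean): x = a + b·m; the corrected spectrum is
  (x − a)/b.  The reference is stored with the fitted correction and reused
  for validation data, never refitted.
* **SNV-DT.** Per spectrum: subtract the mean and divide by the SD (SNV),
  then remove a fitted 2nd-degree polynomial in wavelength (detrend, via an
  orthonormalised quadratic basis).  Any affine or quadratic trend maps to
  zero.
* **Math treatments** follow the four-integer convention "d,g,s1,s2":
  moving-average smoothing of width s1 → d successive centred gap
  differences y[i] = x[i + g/2] − x[i − g/2] (gap g in grid points) → second
  smoothing of width s2.  The gap difference is the point-difference
  (Norris-style) form; whether the historical software used point
  differences or gap-to-gap block means is not recoverable, and the
  point-difference form is the one implemented.  Even smoothing widths use
  the left-centre window.  Edges where any stage is undefined are trimmed —
  never padded — and the output grid records the trim.  Odd gaps with
  d ≥ 1 are rejected rather than rounded.  Operator order is scatter
  correction first, then treatment.

## Sample selection and splitting

MSC-normalised spectra are clustered by Ward's minimum-variance method on
squared Euclidean distances (scipy linkage).  The tree is cut into `k_main`
clusters (default 6); each cluster larger than `small_cluster_max` (default
4) is Ward-re-clustered into up to `k_sub` (default 5) sub-clusters; each
sub-cluster contributes its centre member (nearest the centroid) and its
`n_boundary` most extreme members; small (sub-)clusters contribute everyone.
The study pipeline derives `n_boundary` from a target size:
round(target/(k_main·k_sub)) − 1, so a 500-sample set with target 180 takes
5 boundary members per sub-cluster and yields ≈180 selections.

The 2:1 calibration/validation split sorts the analysed samples ascending by
the trait (ties broken by sample ID) and sends the middle member of each
complete rank triplet (ranks 2, 5, 8, …) to validation: validation size is
⌊n/3⌋, the global extremes always stay in calibration, and the validation
range is contained in the calibration range.  For 180 samples this gives
120 calibration and 60 validation samples.

## Calibration

X and y are mean-centred, not variance-scaled (the spectroscopy convention).

* **PLS** is NIPALS PLS1 with standard deflation; at full rank it coincides
  with ordinary least squares (tested against both OLS and scikit-learn's
  PLSRegression).
* **MPLS** ("modified" PLS) standardises the X-residual columns and the
  y-residual by their current standard deviations when forming the weight
  vector for each successive factor; scores, loadings and deflation stay in
  the unstandardised space.  The historical vendor algorithm is unpublished;
  among the defensible readings of "residual standardisation" this one
  reproduces the field's experience that MPLS is stable and performs within
  a few percent of PLS (the fully-standardised-space alternative degrades
  cross-validation error by 20–40 % on the synthetic set by amplifying
  noise-dominated residual channels).  The implementation is
  compatible-in-spirit, not bit-compatible, with the vendor's.
* **PCR** regresses y on the leading PCA scores of centred X.

Factor count is chosen by contiguous-block cross-validation (default 4
blocks, deterministic, no shuffling): SECV(k) is the RMSE of pooled held-out
predictions with k factors and the chosen count is the SECV argmin subject
to a hard cap (default 5 — the conventional ceiling for ~120-sample
calibrations; smaller k wins ties).  SEC uses the n − 1 − k denominator.

**Outlier elimination** is iterative: samples with standardised y-residual
|t| > 2.5 or score-space Mahalanobis leverage GH > 3 (normalised so the
average is ~1) are removed and the model refitted, at most 2 passes, total
removals capped at 10 % of the starting samples.  Hitting the cap warns and
stops; it never raises.  External validation never removes outliers.

## Validation statistics

With x₁ predicted, x₂ measured, and n validation samples:

* bias = mean(x₂ − x₁) (signed; positive = model underestimates);
* SEP = √(Σ(x₁ − x₂ − b)²/n), with b = bias for the bias-corrected SEP(C)
  and b = 0 otherwise; the denominator is n (a flag exposes n − 1 for
  comparison with other software).  SEP² = SEP(C)² + bias² exactly;
* RPD = SD(x₂)/SEP, classified <1.0 very poor, 1.0–1.4 poor, 1.4–1.8 fair,
  1.8–2.0 good, 2.0–2.5 very good, ≥2.5 excellent;
* RSQ is the squared Pearson correlation and slope the OLS slope of
  predicted on reference;
* the paired t-test uses d = lab − predicted, sample SD (n − 1), SE =
  SD/√n, t = mean/SE, df = n − 1, two-sided p from Student's t, 95 % CI.

Both SEP and SEP(C) are reported; a config switch (`rpd_from`, default
`sep_c`) selects which one enters RPD, since validation tables in this
field are ambiguous about the convention.

## Grid search and ranking

The default search grid crosses 17 historical treatment codes × 3 scatter
options (SNV-DT, MSC, none) × 3 regression methods (153 cells per trait,
searched independently per trait).  Cells that fail (e.g. a treatment whose
edge loss empties the grid) are recorded as data, not errors.  Ranking
maximises external RSQ, breaking ties by higher RPD then lower SEP; the
criteria lack a canonical total order, so the ordering is exposed in config.
Ranking is invariant to grid enumeration order.

## Problem sizes used in tests and reproduction runs

The standard fixture is 500 accessions on the 1,046-point grid (seed 42).
The full-pipeline recovery check and the reproduction script search the
trait-winning treatment codes (4,8,8,1; 3,16,8,2; 4,6,6,1; 2,8,8,1) crossed
with all scatter and regression options — 36 cells per trait — which keeps a
complete run under half a minute while still exercising every method;
`GridSpec()` restores the full 17-treatment screen.  Smaller unit fixtures
use 60–150 samples.

## Known limitations

* The JCAMP-DX reader handles plain AFFN `(X++(Y..Y))` tables only; no
  compressed (ASDF/DIF-DUP) ordinates, no vendor binary formats.
* PLS2 (multi-trait), variable selection, Savitzky–Golay derivatives and
  weighted/inverse MSC variants are out of scope.
* Ward tie-breaking follows scipy's deterministic order; on data with exact
  ties the brute-force definition may merge in a different order.
* The RPD classification bands are conventions, not statistics; they carry
  no uncertainty.
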
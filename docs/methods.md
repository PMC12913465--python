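# Methods

This note records the models, conventions and numerical choices behind
`heatspec`, in the spirit of the methods documentation of statistical
packages: what is computed, under which assumptions, and where a
convention had to be chosen.

## The synthetic experiment

The generator (`heatspec.synthetic_data`) stands in for a paired
pot experiment: a control group (CK) growing naturally and a treatment
group (T) heated from below, each with `n_per_group = 40` canopy
samples per growth stage (branching, budding, flowering), spectra on a
1-nm grid from 350 to 1350 nm. It is phenomenological by design — no
leaf/canopy radiative transfer, no soil or illumination geometry, no
water bands beyond 1350 nm.

A latent state per sample drives everything: chlorophyll, stress and
canopy-structure levels, all in [0, 1]. The noiseless reflectance is a
mixture of a visible template and a NIR plateau switched by a logistic
red edge:

    L(λ) = 1 / (1 + exp(−(λ − λ_re)/10)),   λ_re = 715 + 20·chl
    V(λ) = (0.08 − 0.04·chl) + 0.06·(1 − 0.5·chl)·exp(−(λ−550)²/(2·30²))
    P    = 0.30 + 0.15·structure + 0.08·stress
    R(λ) = V(λ)·(1 − L(λ)) + P·L(λ)

so healthier (higher-chlorophyll) canopies have a longer-wavelength red
edge, a darker red/blue baseline, and a flatter green peak, while
stress raises the NIR plateau — the qualitative contrast the analysis
is supposed to detect. Noise has two parts: a smooth multiplicative
perturbation (random cubic in the normalised wavelength, coefficient sd
`noise_sd_smooth/2`, default `noise_sd_smooth = 0.01`) emulating
calibration/illumination drift, and i.i.d. additive noise (sd 0.002).
Values are clipped to [0, 1]. These defaults keep optimal-band recovery
solvable but not trivial; both are config fields.

The seven indicators are affine in the latent state plus Gaussian
noise, truncated to admissible ranges (non-negative; Fv'/Fm' and qP in
[0, 1]). Stress slopes are negative for SPAD, A, gsw, Ci, Fv'/Fm' and
qP and positive for qN; the noise sd of each indicator is 5 % of its
plausible range. Intercepts and slopes (`DEFAULT_COUPLING`) were chosen
once to land each indicator in a realistic range for a temperate forage
legume (SPAD 20–50, A 5–23 µmol m⁻² s⁻¹, gsw 0.05–0.45 mol m⁻² s⁻¹,
Ci 150–280 µmol mol⁻¹, quantum yields and quenching coefficients below
1 / around 1).

Stage structure: treatment stress is drawn uniformly from
(0.1, 0.4) at branching, (0.4, 0.8) at budding and (0.5, 0.8) at
flowering — effects strengthen with stress duration, giving the later
stages the stronger signal. Chlorophyll and structure baselines rise
into budding (0.55/0.75/0.65 and 0.35/0.60/0.70); chlorophyll is pulled
down by 0.35 per unit stress; per-sample latent jitter is N(0, 0.08).
Samples are tagged with pseudo-dates (5 + 5 + 4 per stage) so that the
per-date η report has the shape of a multi-date campaign.

What passing tests on this generator do **not** show: robustness to
real-world canopy effects (view/illumination geometry, soil background,
water-band absorption, instrument-specific noise spectra, morphological
change across stages). The generator's couplings are conventions, not
estimates — no public dataset from such an experiment exists to
calibrate against — so model scores on synthetic data are qualitative
analogues, not predictions of field performance.

## Preprocessing conventions

* Canonical grid: integer nm, 350…1350 (1001 bands). Resampling is
  linear interpolation with duplicated input wavelengths collapsed to
  their mean first; extrapolation is refused.
* Savitzky–Golay smoothing: window 11, polynomial order 2 (standard for
  1-nm vegetation spectra; overridable). Ends use the truncated-window
  polynomial fit (`mode="interp"`), so polynomials of degree ≤ order
  are reproduced exactly everywhere.
* FDR: central differences on interior bands, one-sided at the two
  ends (exact for linear spectra). An SG-derivative variant is offered
  behind `method="savgol"`; the central-difference form is canonical
  because it is the simplest reproducible convention and the tests are
  robust to either choice.

## Trilateral parameters

Twenty parameters per spectrum: for each of the red (680–780 nm), blue
(490–530 nm) and yellow (560–640 nm) edges the FDR extreme (amplitude)
and its wavelength (position), the FDR area; green-peak (510–560 nm)
maximum and red-valley (640–700 nm) minimum reflectance and positions;
and seven ratio/normalised-difference combinations. Only the red-edge
window is fixed by convention in the source literature; the remaining
windows follow prevailing usage and are configurable.

Deliberate conventions, since amplitude/area sign conventions are not
standardised:

* `Dy` keeps its sign (extremum of |FDR|; the derivative is typically
  negative on the yellow edge and negative correlations with Dy are
  meaningful).
* `SDr`, `SDb` integrate signed FDR; `SDy` integrates |FDR| so all
  areas are positive and ratios such as SDr/SDy are well defined.
* argmax/argmin ties break toward the shorter wavelength.
* Ratio fields are NaN when their denominator is zero; a constant
  spectrum yields all-zero D/SD values with flagged ratios.

## Band selection

Per-band Pearson correlation spectra use the standard product-moment
formula; zero-variance bands get r = 0 with a flag, a constant
indicator is an error. Top-k (default 10) picks sort by |r| descending,
ties toward the shorter wavelength.

SPA: columns are mean-centred and unit-scaled before projection
(standard chemometrics practice, switchable). Each iteration
residualises every unselected column against the most recent pick and
selects the largest residual norm; because candidates stay
residualised, this equals successive orthogonalisation against the
whole selected set — verified index-for-index against a literal
per-candidate projection loop. A selection whose remaining candidates
all have (numerically) zero residual is reported as degenerate rather
than silently continuing, since standardised n-sample data has rank at
most n − 1.

The (k(0), N) sweep scores each candidate selection by seeded K-fold
(default 5) OLS RMSECV, pooled over folds. Two numerical choices make
the minimiser exactly reproducible: CV design matrices use the sorted
selection (OLS is column-order invariant, so equal selection sets tie
bit-exactly) and ties break toward smaller N, then smaller k(0).
Rank-deficient folds fall back to a tiny ridge (1e-8). Cross-validation
replaces the original 50/50 calibration/prediction split because that
partition is not recoverable; the holdout structure can still be
emulated by splitting before calling the optimizer.

## Two-band index search

Formulas are the universal ratio / normalised-difference / difference
forms. The search is exhaustive over ordered pairs on the (optionally
strided) grid, maximising |r|; the signed r is reported. Pairs with an
undefined index (zero denominator) for any sample are skipped and
counted. NDVI/DVI are antisymmetric — swapping the bands negates the
index — so each optimum has an exact-|r| twin; the result is
canonicalised to the smaller first wavelength, which also makes the
vectorised search agree exactly with a naive double loop. The full
1001-band search is vectorised one pair-row at a time and runs in
seconds per indicator.

## Regression models

* ε-SVR, RBF kernel, ε = 0.01; C ∈ {0.1, 1, 10, 100} and γ on a
  5-point log grid 1e-3…10 chosen by a seeded internal 5-fold grid
  search (RMSE scoring); features standardised with training-set
  statistics.
* Random-forest regression: 200 trees, minimum leaf 5, seeded
  bootstrap.
* PLSR: components by internal CV, capped at min(10, features,
  n_train − 1); features standardised.

A constant training target short-circuits to a constant predictor for
all three families. Splits are seeded uniform 3:1 draws
(floor(n/4) test samples). Selectors (top-10, SPA, index pairs, the
|r| > 0.6 trilateral filter) are fitted on the training partition only;
a `paper_mode` flag fits them on all data for comparability with
workflows that select features before splitting. Test R² uses the
test-set mean in the denominator (the train-mean convention is
available via `baseline_mean`). RMSE is computed on raw indicator
units. Model-ranking claims (e.g. SVR above PLSR above RFR) are
reported, never asserted, since the ordering is data-dependent.

## Pipeline and reporting

`run_full` simulates (or accepts) per-stage tables and runs, per stage,
group and indicator: preprocessing → trilateral extraction →
correlation and SPA selection (original + derivative) → all six index
searches → the model × feature-set grid. Per-cell seeds derive from the
run seed and the (stage, group, indicator) labels via CRC32, so reruns
are byte-identical. Stage indicators default to the stage-sensitive
sets (SPAD/gsw/qP at branching and flowering, SPAD/A/qN at budding).
Reports: per-stage tables mirroring the band/index/model summaries, the
CK→T red-edge shift with a red/blue-shift label, Dr/SDr stage
orderings, per-date and stage-mean η, and the best-feature tally.

Problem sizes: the default analysis uses the full 1-nm grid for index
searches and a 5-fold stride for SPA; the bundled acceptance script and
the end-to-end tests run band searches on a 5-nm stride (201 bands) and
SPA on a further 5-fold stride, which preserves the structure of the
result while keeping a full three-stage run in the minutes range on one
core. The test suite uses coarser strides still (10–20 nm) for the
orchestration checks; all stride choices are config fields, not
hard-coded.

## Known limitations

* The generator's realism limits are listed above; in particular the
  stage-to-stage trends are builtin conventions, so cross-stage
  comparisons on synthetic data test plumbing, not biology.
* SPA's k(0) sweep is O(bands² · N) and becomes slow on the full 1-nm
  grid; the stride option is the intended mitigation.
* The exhaustive pair search optimises training-set |r| only; with few
  samples the selected pair can overfit, which is why all reported
  model scores come from the held-out partition.
* Vendor spectrometer binary formats are out of scope; data enter as
  CSV (wide or long dialect, fraction or percent reflectance).
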
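# Methods

## The generative model

Every synthetic exocarp spectrum is an additive model on a uniform grid
(700–1400 cm⁻¹, step 0.5 cm⁻¹ by default):

    I(x) = b(x) + Σₖ Aₖ · exp(−(x − μₖ)² / 2σₖ²) + ε(x)

with a smooth non-negative baseline `b` (a gentle quadratic plus one very
broad Gaussian hump, σ = 300 cm⁻¹, standing in for the fluorescence
background), i.i.d. Gaussian detector noise ε, and one Gaussian band per
vibrational component. Default band width is σ = 5 cm⁻¹ (FWHM ≈ 11.8 cm⁻¹),
which makes the 1318/1325/1333 cm⁻¹ cluster overlap heavily enough that only
deconvolution can separate it — the regime the analysis is designed for.
Default noise is 1% of the ripe-class carotene (P3) amplitude.

Two band libraries are built in. The four-class library (`sample_A`) uses
single published positions (1244, 1258, 1281, 1306, 1318, 1325, 1335,
1357 cm⁻¹) and per-class mean intensities taken verbatim from the tabulated
four-class study data, with dashes encoded as zero amplitude (no
guanine/cytosine when unripe, no chlorophyll-a when over-ripe, tryptophan
only when unripe). The three-class library (`sample_B`, the classifier's
dataset: 13 under-ripe, 19 ripe, 15 over-ripe fruits) imposes a shared
per-class gain on the six proportional bands: the under-ripe column is the
base and the gains 1.00 / 1.70 / 2.25 are the ratios of the carotene (P8)
class means 334 / 568 / 750 a.u. This construction makes intensity *ratios*
class-independent by design, so ANOVA can select band intensities but not
ratios. The lipid band centre drifts 1298 → 1301 → 1304 cm⁻¹ with ripeness
(inside the printed 1297–1305 range), making its *position* the one
significant position feature. Chlorophyll-a (P6) has zero amplitude in all
three classes; tryptophan (P7) has a class-independent mean of 174 a.u.
(grand mean of its printed class values) with high scatter (cv 0.30), so it
carries no ripeness signal. A `full_range` library adds chlorophyll-a bands
at 744/915/986 cm⁻¹ with amplitudes decaying to zero through ripening, for
reference-peak location on raw spectra.

### Within-class variability (a calibrated fixture)

The published tables give single per-class values with no dispersion, so
between-fruit variability is necessarily invented. Each fruit draws a shared
multiplicative gain (cv 0.05) coupling all its bands, an independent relative
amplitude jitter per band (cv 0.05; 0.30 for tryptophan), a centre jitter
(sd 0.5 cm⁻¹; 1.0 cm⁻¹ for the drifting lipid band) and a relative width
jitter (cv 0.06, ≈ 0.7 cm⁻¹ FWHM scatter). These four numbers are a
*calibrated fixture*: they are chosen, once, so that the default cohort
reproduces the study's qualitative outcome — cleanly separable classes and an
ANOVA that flags the six proportional band intensities plus the lipid
position and nothing else. Two consequences worth knowing:

- With larger gain scatter (cv ≳ 0.10) the ripe/over-ripe log-gain gap
  (ln 2.25/1.70 = 0.28) is only ~2.7 sd, borderline fruit appear in most
  cohorts, and neither the near-perfect accuracy nor the very low validation
  cross-entropy is reproducible. The study's own headline numbers (46/47
  correct, validation cross-entropy 0.04) imply its features were cleanly
  separable; the calibration encodes that.
- With *zero* width variability the within-class FWHM variance is pure fit
  noise (~0.3 cm⁻¹), so sub-1% SNR-dependent width-estimation biases become
  statistically significant class effects and FWHM features leak into the
  selection. Real bandwidths vary between fruit; cv 0.06 restores that.

What the generator deliberately does not emulate: cosmic-ray spikes,
wavenumber miscalibration, multiplicative scatter, detector nonlinearity,
non-Gaussian lineshapes and day effects. Passing tests therefore demonstrate
the pipeline's correctness on well-behaved spectra with a smooth additive
background, not robustness to every instrumental artifact.

## Preprocessing

Baseline estimation is asymmetric least squares (a Whittaker smoother with
asymmetric weights: p = 0.01 above the baseline, 1 − p below), the standard
choice for fluorescence backgrounds under sharp Raman peaks. The roughness
penalty is λ = 1e8 at the 0.5 cm⁻¹ grid. λ trades bias for flexibility
through an effective smoothness scale ≈ λ^(1/4) grid steps: at 1e8 that is
~50 cm⁻¹ — stiff enough not to bend up under the 120 cm⁻¹-wide band massif
(which would strip the components' wings and bias amplitudes low by tens of
percent), flexible enough to track the σ = 300 cm⁻¹ fluorescence hump. The
corrected spectrum plus the returned baseline reconstructs the input exactly.

Savitzky–Golay smoothing defaults to an 11-point cubic window (≈ 5 cm⁻¹),
preserving ~12 cm⁻¹-FWHM peaks with < 2% distortion; edge values come from
the polynomial fitted to the first/last full window. Smoothing is applied
for display and raw-spectrum peak location, but the deconvolution fit runs
on the *unsmoothed* baseline-corrected band: a linear filter adds no
information to a least-squares fit, while the correlation it induces
(~1 window) invalidates residual-based inference — the noise estimate, the
reduced χ², and the component significance tests would all be optimistic,
and smooth noise bumps of exactly the filter's width mimic narrow components.

Reference peaks on raw spectra are located as the local maximum nearest the
queried position within a ± window, requiring prominence above 3× a robust
noise scale (1.4826·MAD of first differences / √2); below that the band is
reported absent, reproducing the dashes of sparse intensity tables.

## Deconvolution

The 1240–1360 cm⁻¹ band is fitted as a fixed eight-component Gaussian
mixture by bounded trust-region least squares (analytic Jacobian; tolerances
1e−14, so noiseless in-model spectra are recovered to ≲1e−6 relative).
Centres are constrained to ±6 cm⁻¹ windows that pin each component to its
molecular assignment; amplitudes are non-negative; σ ∈ [1.5, 15] cm⁻¹.
Initial amplitudes come from non-negative least squares with centres and
widths frozen at their nominal values — linear, cheap, and it prevents
overlapped neighbours from double-counting height. Window centres differ by
cohort: the four-class analysis uses the single published positions; the
three-class analysis centres windows on the published band *ranges*
(midpoints 1247, 1263.5, 1280.5, 1301, 1318.5, 1325, 1333, 1352.5), because
a ±6 window around 1306 would exclude the under-ripe end of the drifting
lipid band and force a cascading misfit through the 1318–1333 cluster.

Pruning marks a component absent when its amplitude is below 3× the noise
scale (estimated robustly from the residuals when not supplied, with a
relative floor of 1e−6 of the largest amplitude for noiseless data), then
applies backward elimination with a partial F-test at α = 1e−4: the
surviving model is refitted without one candidate component at a time and
the component whose removal costs least is dropped if the cost is not
significant. This second criterion exists because in this heavily overlapped
band a spurious component can carry large amplitude along a nearly
degenerate direction of the least-squares surface (typically impersonating a
neighbour while pinned against its window bound); statistical ties are
broken against the component whose fitted centre strayed farthest from its
nominal window centre. Survivors are refitted; pruned components are kept in
the peak list with `present=False` and render as dashes.

A caveat the demo tests make explicit: at the default cohort noise, three
σ = 5 bands spaced 6.5 and 8 cm⁻¹ apart (guanine/cytosine, chlorophyll-a,
tryptophan) are not jointly identifiable — removing any one of the three
changes the fit within noise. That is the statistical reason the
chlorophyll-a component prunes away in the three-class cohort, and why the
eight-components-retained demonstration uses a spectrum at one fifth of the
cohort noise.

Reduced χ² is the residual sum of squares over the noise variance and the
residual degrees of freedom (N − 3·components); with the known generator
noise it sits near 1 on default fixtures.

## Features and selection

Each fruit yields exactly 27 features in a fixed canonical order: intensity,
gravity centre and FWHM for P1–P5, P7, P8 (21), plus the five intensities
relative to the carotene reference P8 and the β-carotene/carotene ratio
P2/P3 (6). Chlorophyll-a is excluded as unreliable. Absent components
contribute intensity 0 and their nominal window centre as position; their
FWHM and any ratio with an absent denominator are missing values, excluded
listwise from that feature's ANOVA only. Integrated area is computed in the
peak table but is not one of the 27; the published feature list is not
itemized, and this schema is one consistent realization of "FWHM, peak
intensity, peak position, and intensity ratio".

Selection uses the classical one-way F-test per feature with a Bonferroni
threshold α/27 (α = 0.05 ⇒ 0.00185). Bonferroni was chosen over no
correction so that "exactly seven significant features" is a stable outcome
rather than a seed accident; under label permutation the expected selection
count is 27 · α/27 ≈ 0.05. Degenerate cases (zero within-group variance)
report F = 0, p = 1 when group means coincide and F = ∞, p = 0 otherwise,
with a flag.

## Classifier

The network is 7-20-3: logistic-sigmoid hidden layer, softmax output,
one-hot targets, mean cross-entropy per sample. Training is full-batch
gradient descent with a backtracking step: a step that would increase the
training loss is halved and retried, an accepted step grows the rate by 10%,
so the training curve is non-increasing by construction. Maximum 200 epochs.
The validation set (5 fruits) is used to select the best epoch and restore
those weights; the no-improvement patience defaults to the full epoch budget
because a 5-sample cross-entropy is far too noisy to gate training on —
plateaus and wiggles trigger premature stops two orders of magnitude above
the reachable validation loss, while best-weight restoration already
provides the overfitting protection early stopping is meant for. Patience is
configurable and smaller values behave as expected.

The 60/10/30 split uses largest-remainder rounding (47 → 28/5/14, i.e. 33
fruits to train + validate and 14 to test) and is stratified by class, since
an unstratified 5-fruit validation set frequently misses a class entirely.
Per-class allocations are reconciled against the global sizes by moving
single fruits between partitions. Features are standardized to zero mean and
unit variance with statistics from the training partition only;
zero-variance columns are left unscaled and flagged. Missing feature values
(from pruned components) are imputed with the column mean before splitting.
Prediction is the argmax of the softmax; ties resolve to the lower class
index. Accuracy is reported as trace/total, in percent to one decimal; the
combined matrix is the elementwise sum of the train, validation and test
matrices. If selection returns nothing (tiny degenerate cohorts) the
classifier falls back to the seven band intensities with a warning.

## Reproducibility and problem sizes

One run seed fans out to the stages through fixed offsets (cohort +0,
deconvolution +1000 +sample index, split +2000, network init +3000), so any
stage can be re-run in isolation and a full rerun is byte-identical. The
default study size is the 47-fruit cohort on a 1401-point grid; a full
pipeline run takes ~10 s on one CPU and the test suite ~30 s, dominated by
the per-fruit mixture fits and the elimination refits. Property tests that
sweep replicates use 12-fruit cohorts; the permutation null uses 200 label
shuffles of the default cohort's feature table.

## Known limitations

- Within-class dispersions are invented (see above); absolute per-class
  means for under-/over-ripe classes are approximated through the shared
  gains, not matched to the printed values.
- The partial-F pruning assumes approximately white residual noise; it is
  run on unsmoothed data for that reason and would be anticonservative on
  smoothed input.
- The reported "gravity centre" of a component is the fitted Gaussian mean
  (for a Gaussian the centroid equals the mean); asymmetric real bands would
  need a separate centroid definition.
- The classifier is intentionally minimal: no hyperparameter search, no
  regularization beyond early stopping, no alternative models.
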
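# Methods

This note documents the models, parameter choices and numerical
decisions behind `radarvitals`, and what the synthetic phantom does and
does not establish about real recordings.

## Displacement reconstruction

An interferometric CW radar maps radial target motion onto the phase of
its complex baseband, `φ(t) = 4π d(t)/λ` with `λ = c/24 GHz ≈ 12.49 mm`;
half a wavelength of motion (≈ 6.246 mm) advances the phase by a full
turn, so breathing-scale motion wraps several times.  Reconstruction
assumes the dominant distortions are *static over the fit interval*:
a complex offset (cross-talk), a quadrature gain ratio and a rotation,
which together turn the ideal circle into a fixed ellipse.

* **Ellipse fit.** Direct algebraic least squares with the
  ellipse-specific constraint `4ac − b² = 1`, in the numerically stable
  two-block formulation, after centring/scaling the points for
  conditioning.  Non-iterative and deterministic; degenerate inputs
  (fewer than 6 points, collinear points, non-ellipse conics) raise
  explicit errors.  The fit is reliable when the samples span at least
  about half the circle — breathing-scale motion covers it many times
  over.  Residual is the RMS algebraic distance under unit-norm conic
  coefficients.
* **Normalization.** One invertible affine map (translate, rotate,
  scale the principal axes to 1, rotate back), recorded in provenance
  metadata.  The map cannot flip orientation, so the sign convention
  (increasing distance ⇒ increasing phase) survives normalization.
* **Demodulation.** Four-quadrant arctangent plus unwrapping (±2π
  whenever consecutive raw phases differ by more than π).  A
  zero-magnitude sample has no argument and is reported by index rather
  than silently patched.
* **Anchor.** The radar measures relative distance only; `d(0) = 0` by
  convention.  Comparisons against ground truth therefore allow an
  arbitrary constant offset.
* **Block-wise refitting** (optional, default off): the ellipse is
  re-estimated when the windowed mean modulus — a proxy for receive
  power — drifts more than 20% from the block of the last fit.  Off by
  default because static scenes are the common case and refitting makes
  runs harder to compare.

## Band splitting

Fourth-order Butterworth designs, stored as second-order sections for
stability at extreme cutoff/rate ratios.  Respiration lowpass 0.5 Hz and
bandpass 0.05–0.5 Hz run on a copy decimated to 100 Sa/s; heart sounds
16–80 Hz stay at the raw rate (default 2000 Sa/s); the sphygmogram band
defaults to 0.75–5 Hz — that band has no reference value in the source
measurement literature and is exposed as configuration.

Application is zero-phase (forward–backward) by default so that beat and
breath timing carries no group delay; a causal mode exists for streaming
parity.  Two numerical choices matter at the 0.05 Hz corner, whose
impulse response spans tens of seconds:

* decimation uses polyphase resampling with **linear-extension padding**
  (zero padding would turn the record's arbitrary DC offset into an edge
  step that rings through the slow filters);
* bandpass inputs are **demeaned first** (a bandpass removes DC in
  steady state anyway) and forward–backward filtering uses an edge pad
  of about three corner periods instead of scipy's short default.

Records shorter than ~10 s are flagged (`edge_warning`): the slowest
corner's transient then dominates.  Residual cross-band leakage is below
1% in energy on phantom scenes.

## Respiration-rate estimators

All four estimators work on zero-centred, bandpass-filtered 30 s
windows (non-overlapping by default; the window length matches the
reference analysis convention).  Undefined outcomes (no peak, fewer than
two crossings) are NaN flags, excluded pairwise from RMSE.

* **ACF**: the raw finite-window autocorrelation sum, largest *local*
  maximum at lags of 3–30 s (the admissible breath periods), ties broken
  toward the longer lag.  The finite-window taper biases the peak a few
  samples early — ≤ 0.1 BrPM on 30 s windows; kept because the plain sum
  is the defined estimator.  Note the 3 s floor makes ACF (and
  peaksearch, below) blind above 20 BrPM even though the filter passes
  30 BrPM.
* **Peaksearch**: maxima and minima with 3 s minimum separation and a
  prominence threshold of 10% of the window peak-to-peak (the threshold
  value is a package choice; only its existence is prescribed).  Mean
  inter-maximum and inter-minimum spacings are averaged.
* **Zero crossing**: sign-change locations; `RR = 60·Fs/(2·mean ΔZC)`.
  An optional dead band (default off) of a few percent of the window SD
  suppresses ripple-induced crossings; off matches the literal
  sign-change definition.
* **FFT**: Hann window, zero-padded to ≥ max(4096, 8·N) rounded to a
  power of two — the native 30 s grid is 2 BrPM, far coarser than the
  sub-BrPM errors the method is expected to resolve, so padded
  interpolation is assumed.  Ties break toward the lower frequency.

Waveform similarity is the normalized cross-correlation maximum with its
signed lag; positive lag means the radar leads (the reference waveform,
a different physical quantity, typically trails by ~0.1–0.2 s).

## Heartbeat detection

**Heart-sound HSMM.**  Three envelope features per 20 ms frame (50 Hz):
homomorphic envelope (exponentiated lowpassed log analytic envelope),
Hilbert envelope, and a band-power envelope; each z-normalized per
record.  A flat record would otherwise have its resampling ripple
z-amplified into fake structure, so near-constant features are zeroed.

The model has four states in fixed cyclic order S1 → systole → S2 →
diastole with Gaussian emissions (full covariance, ridge-regularized)
and truncated-Gaussian sojourn priors: S1 120 ± 30 ms, S2 100 ± 25 ms,
systole and diastole derived per record from an autocorrelation estimate
of the heart cycle (largest envelope-ACF peak at 0.5–2 s lags; S1–S2
spacing from a secondary peak at 0.2–0.5 cycle).  Emissions are trained
supervised on labelled synthetic phonocardiogram scenes generated at
fixed seeds — a self-contained realization that is faithful in structure
to published duration-HSMM segmenters but not bit-identical to any of
them (the originals' logistic-regression emissions and public training
corpora are out of scope).

Decoding is an exact duration-dependent Viterbi dynamic program,
O(T·S·D).  The first and last segments are censored by the record edges
and are scored with the sojourn survival function instead of the exact
pmf — without this the decoder squeezes spurious short cycles against
the record end.  Beats are the onsets of decoded S1 runs, gated: a run
is kept only if its median S1 emission log-likelihood strictly exceeds
the record's median per-frame S1 log-likelihood (plus a rounding-safe
margin).  Genuine S1 bursts sit far above the diastole-dominated median;
in silence every frame is identical and nothing clears a strict
threshold, so the beat count is zero.

**Sphygmogram template matching.**  A beat template is ensemble-averaged
over prominent periodic extrema of a 10 s training prefix (periodicity
from the prefix autocorrelation at 0.33–2 s lags) and slid across the
record as a Pearson correlation computed with cumulative sums; maxima
above 0.5 separated by a 0.35 s refractory period are beats.
Normalization makes the detector insensitive to amplitude modulation,
but beat *timing* still rides on the pulse waveform, which trails the
electrical beat by the pulse transit time.

**IBI comparison.**  Intervals are paired over consecutive *matched*
beats, skipping pairs separated by an unmatched reference beat so a
missed beat cannot create a double-length interval.  Template-matching
beats are paired to R-peaks with a 300 ms window (the ~150 ms transit
delay is a constant offset that cancels in intervals); the 75 ms
tolerance is reserved for heart-sound scoring, where it defines TP/FP/FN.

## Evaluation conventions

* ±75 ms is a closed interval; matching is one-to-one, greedy
  closest-first over all candidate pairs (ties in distance resolved by
  earlier reference time).
* Scores are percentages to two decimals.  TP = 0 with non-empty
  denominators gives 0; a missing denominator gives NaN.
* Cohort SDs use the sample convention (n−1); the 2-SD exclusion rule
  removes subjects strictly below `mean(F1) − 2·SD(F1)` and recomputes
  both aggregates on the remainder.  With one subject the SD is
  undefined and the rule is skipped.
* The KS comparison and the synchronization alignment delegate to the
  standard two-sample KS test and normalized cross-correlation
  (resampling to the higher rate first); an alignment whose peak
  correlation is below 0.5 is flagged low-confidence.

## The phantom: what it emulates, and what it does not

Defaults describe a resting adult measured frontally: breathing
4–12 mm peak-to-peak at 3–30 BrPM (asymmetric raised-cosine breaths,
inspiration 40% of the cycle; pure sinusoid available for analytic
tests), per-breath period CV 8% and depth CV 15% when jitter is enabled,
optional apnea intervals with a 0.25 s taper; heart rate with per-beat
CV ~3%; Gaussian-windowed heart-sound wavelets (σ = 12 ms, carrier
40 Hz, S1 50 µm / S2 30 µm, S2 delayed 0.3 s); a pulse-wave bump of
0.3 mm trailing each beat by 150 ± 10 ms with 20% amplitude CV (the
surface pulse is mechanically decoupled from valve closure — this
timing looseness is what makes sphygmogram beat detection inherently
noisier than heart-sound segmentation); and band-limited non-respiratory
body motion (postural sway, vasomotion) at 0.4 mm RMS inside
0.05–0.5 Hz, visible to the radar but not to an impedance reference.
Without such in-band disturbance the phantom's breathing is so smooth
that peak and crossing timing are both near-exact; with it, the
mechanism that favours zero crossings over peak search in practice
(steep crossings keep their timing precision, flat extrema lose it)
operates on the phantom as well.

The channel model distorts the ideal circle by gain ratio, rotation and
offset, then adds complex white noise with per-quadrature SD
`A·4π·σ_d/λ`, so an ideal demodulator on a static target reproduces the
configured displacement SD (default 1.07 µm, the bench precision of the
system class emulated).  The electromechanical ECG-to-S1 delay defaults
to 40 ms (configurable; not a reported quantity).  Detector
common-mode offsets are constants per channel; an optional
periodic-in-phase gain ripple emulating detector nonlinearity is off by
default.

Not emulated: motion artifacts of a non-cooperative subject, multipath
and clutter, waveform morphology changes (e.g., murmurs, arrhythmia),
electrode noise in the references, thermal drift.  Passing phantom tests
therefore establishes the correctness of the processing chain under the
stated signal model, not clinical performance; the bundled study tables
are the package's contact with real data, and they are reproduced at the
aggregate level only.

## Problem sizes in the test suite

The suite favours many short seeded scenes over few long ones: 20–30 s
scenes for beat detection (20 seeds, heart rates 50–100 BPM), 150 s
respiration scenes at a reduced 240 Sa/s raw rate (20 seeds) for the
estimator-ordering regression, and 100 000 samples for the static noise
calibration.  These sizes give stable aggregate statistics while keeping
the whole suite under a minute of CPU.
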
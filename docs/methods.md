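# Methods

## Problem and pipeline

Heart rate variability (HRV) is the beat-to-beat variation in the
intervals between heartbeats; it reflects autonomic nervous activity and
is traditionally measured from the ECG R waves. Chest-mounted inertial
sensors offer two mechanical alternatives: the seismocardiogram (SCG,
linear acceleration) and the gyrocardiogram (GCG, angular velocity),
whose aortic-valve-opening (AO) wave is a sharp peak that follows each R
wave within roughly 100 ms and can serve as the beat fiducial instead.
`cardiohrv` implements the full comparison pipeline:

1. **R detection** — Pan–Tompkins on the ECG.
2. **AO detection** — the maximum of the SCG z-axis (back→chest) or GCG
   y-axis (head→foot) channel in a window after each R wave.
3. **Interval series** — consecutive fiducial differences per modality,
   in ms.
4. **Indices** — 11 HRV indices per subject and modality.
5. **Cohort statistics** — mean±SD tables, two-sample t-tests and
   cross-modality Pearson correlations for a healthy vs.
   valvular-heart-disease (VHD) two-cohort design.

## Beat detection

Pan–Tompkins is implemented in its classic form with every constant
scaled to the sampling rate: a 5–15 Hz band-pass (2nd-order Butterworth),
five-point derivative, squaring, 150 ms moving-window integration, dual
adaptive signal/noise thresholds with search-back at half threshold when
the gap since the last beat exceeds 1.66× the recent mean RR, a 200 ms
refractory period, and T-wave discrimination by slope comparison inside
360 ms. Two deliberate departures from the 1985 hardware description:
filtering is zero-phase (`sosfiltfilt`, centered kernels), which removes
the need for group-delay bookkeeping, and each detection is refined to
the local maximum of the *raw* ECG within ±40 ms, so reported fiducials
are R-wave samples rather than integrator peaks. Thresholds are
initialised from the first two seconds of the integrated signal.

The AO search window is **forward-only**, `[R, R + 100 ms)`: AO
physiologically follows R. (A symmetric variant, `[R − w, R + w)`, is
available via `detect_ao(..., symmetric=True)` for sensitivity
analyses.) The mechanical channel is band-passed 1–30 Hz (zero-phase)
before the maximum search to suppress baseline drift; ties go to the
earliest sample; beats whose window overruns the end of the signal are
dropped. Detection is invariant to positive affine rescaling of the
channel, so raw sensor counts work as well as physical units.

Interval series are computed from *sample-index differences* divided by
the sampling rate. This makes the cancellation of a constant AO latency
exact in floating point: ECG- and AO-derived interval vectors are then
bit-identical when the latency is constant, which is the backbone of the
cross-modality agreement checks.

## HRV indices

Time domain: AVNN (mean NN, ms), SDNN (sample SD, ms), RMSSD (root mean
square of successive differences, ms), pNN50 (fraction of successive
differences **strictly** greater than 50 ms).

Frequency domain: band powers of the tachogram in VLF 0.0033–0.04 Hz,
LF 0.04–0.15 Hz and HF 0.15–0.4 Hz, plus LF/HF. The spectrum is a Lomb
periodogram — the least-squares spectral estimator for unevenly sampled
series — evaluated directly from its trigonometric sums with the
per-frequency phase origin τ, at 1024 evenly spaced frequencies on
(0, 0.4] Hz. Numerical choices:

* **Normalisation.** The raw periodogram is rescaled so that its Riemann
  sum over the evaluated grid equals the sample variance (ddof=1) of the
  mean-subtracted intervals. Band powers are then in ms² and partition
  the variance captured below 0.4 Hz. Under uniform sampling at Fourier
  frequencies this normalised estimate coincides with the classical
  |DFT|²/N periodogram to machine precision (tested at 1e−6).
* **Band membership** is half-open, `low ≤ f < high`, so the three bands
  partition the grid with no double counting.
* **Detrending** is mean subtraction only; no interval resampling (the
  Lomb method is chosen precisely to avoid it) and no automatic
  ectopic-interval rejection.
* **Degenerate inputs**: a constant series yields an all-zero spectrum;
  zero HF power makes LF/HF an NaN marker, never an exception. A series
  shorter than one cycle of the lowest band (≈303 s for 0.0033 Hz) is
  rejected with the minimum duration in the message.

Nonlinear: Poincaré SD1/SD2. SD1 is the sample SD of
(NN<sub>i+1</sub> − NN<sub>i</sub>)/√2 (spread across the identity line
of the NN<sub>i</sub> vs NN<sub>i+1</sub> scatter, short-term
variability); SD2 is the sample SD of (NN<sub>i</sub> + NN<sub>i+1</sub>)/√2
(spread along the identity line, long-term variability). All SDs use the
N−1 divisor for consistency with SDNN; as a consequence SD1 = RMSSD/√2
holds only asymptotically (the mean successive difference is not exactly
zero in finite samples), and tests assert it as a ≤5 % approximation at
N ≥ 100, not an identity.

## Cohort statistics

Per-cohort tables report mean and sample SD per index, with NaN entries
excluded per index and the effective n reported. Between-cohort tests
are classic pooled-variance (Student's) two-sample t-tests, two-sided at
α = 0.05, chosen over Welch because the method being reproduced names
Student's test; a `welch=True` flag exists. **No multiple-testing
correction is applied** — 33 raw tests (11 indices × 3 modalities) at
α = 0.05, so ~1–2 false rejections are expected under the global null;
this mirrors the study design being emulated and is flagged here rather
than silently corrected. Cross-modality agreement is Pearson's ρ with
"strong" defined as ρ > 0.7 — one-sided by construction, as the rule is
conventionally stated; a perfect negative correlation is *not* strong.
Degenerate cases: equal-mean zero-variance groups give t = 0, p = 1;
zero variance in a correlation vector gives an NaN ρ.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage is testable with per-beat ground
truth. The RR process is

    RR_i = mean_rr + lf_amp·sin(2π·lf_freq·t_i) + hf_amp·sin(2π·hf_freq·t_i) + ε_i

evaluated at cumulative beat times (event sampling, as rhythms appear in
real tachograms), with ε white Gaussian and intervals clamped positive.
Defaults: lf_freq 0.1 Hz, hf_freq 0.25 Hz — the centers of the LF and
HF bands. For a pure two-tone series the interval variance is
(lf_amp² + hf_amp²)/2, which the tests use for parameter recovery.

Rendering places a narrow Gaussian spike (≈20 ms) at each beat time on
the ECG and a wider Gaussian bump (≈30 ms) at R + ao_latency (+ optional
jitter, truncated at ±3 SD so the AO stays inside the 100 ms window) on
the SCG z and GCG y axes; the other four axes carry only noise. A 0.4 s
flat lead-in/out frames the beat train so edge beats are renderable and
detectable. All randomness flows from one integer seed through three
independent bit-generator streams (RR noise, AO jitter, channel noise),
so identical configs give bit-identical output.

Default study conditions for the two-cohort experiment: a healthy cohort
of 29 subjects (mean RR 950 ± 110 ms between subjects, rhythm amplitudes
75/65 ms, beat-to-beat noise 55 ms — SDNN ≈ 90 ms, LF/HF ≈ 1) and a
VHD-like cohort of 30 subjects (mean RR 880 ± 150 ms, HF amplitude 95 ms
and noise 95 ms — markedly larger short-term variability and LF/HF < 1,
the direction of the clinical contrast). Recordings are 330 s per
subject at 800 Hz — just above the ≈303 s floor the VLF band requires —
with a constant 40 ms AO latency.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: P/T waves and realistic QRS morphology,
respiration–heart-rate coupling, 1/f (VLF-dominant) interval dynamics
(synthetic VLF power is only the white-noise floor below 0.04 Hz, far
below clinical values), VHD-specific waveform distortion of the SCG/GCG,
motion artifacts, and ectopic beats. Detection results on this synthetic
data bound the pipeline's correctness, not its clinical robustness.

## Calibration and problem sizes

The type-I-error check draws both cohorts from the same healthy spec and
replicates the experiment 250 times at the interval level (RR generation
→ per-subject AVNN → the same pooled t-test used by the report),
asserting the rejection fraction lies in [0.02, 0.09] at nominal
α = 0.05. Working at the interval level keeps 250 replicates at a
few seconds; rendering and detection contribute nothing to t-test
calibration. Power monotonicity is checked the same way over a
three-point grid of variability ratios.

Unit and acceptance tests run cohort experiments at 256 Hz and ~310–330 s
per subject; the acceptance script runs the full 29 + 30 experiment at
the default 800 Hz. These sizes were chosen to keep a complete run in
tens of seconds while staying above the VLF duration floor.

## Known limitations

* AO detection is ECG-anchored; standalone SCG/GCG beat detection is out
  of scope, as is detection of the other mechanical waves (MC, MO, AC).
* Exact reproduction of published clinical tables is not expected: the
  original analyses depend on toolbox internals (Lomb grid and
  normalisation, detector settings, possible ectopic handling) that are
  not public, and on data that must be downloaded separately.
* The text-dialect reader is the only ingestion path; MATLAB workspace
  containers used by one public VHD dataset must be converted
  out-of-band to the 7-column dialect.
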
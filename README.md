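# cardiohrv

Heart rate variability (HRV) analysis on concurrent electrocardiograms
(ECG), seismocardiograms (SCG, chest-wall acceleration) and
gyrocardiograms (GCG, chest-wall angular velocity).

HRV — the physiological variation in the intervals between consecutive
heartbeats — is classically measured from the ECG R wave. Chest-mounted
inertial sensors capture the heart's *mechanical* activity instead, and
their aortic-valve-opening (AO) wave, a sharp peak on the SCG z axis and
GCG y axis that follows each R wave within ~100 ms, can serve as the
beat fiducial. `cardiohrv` is for researchers who want to test whether
mechanocardiogram-derived HRV agrees with ECG-derived HRV — e.g. across
a healthy cohort and a valvular-heart-disease (VHD) cohort — with every
stage of the chain in one tested package:

* **Beat detection** — Pan–Tompkins R-wave detection (band-pass →
  derivative → squaring → 150 ms integration → dual adaptive thresholds
  with search-back, 200 ms refractory); AO detection as the local
  maximum of the band-passed SCG z / GCG y channel in `[R, R + 100 ms)`.
* **The 11 standard HRV indices** per subject and modality:
  * time domain — AVNN, SDNN, RMSSD, pNN50 (|ΔNN| > 50 ms);
  * frequency domain — VLF (0.0033–0.04 Hz), LF (0.04–0.15 Hz),
    HF (0.15–0.4 Hz) powers in ms² and LF/HF, from a 1024-frequency
    **Lomb periodogram** of the unevenly sampled tachogram

    P(ω) = ½ [ (Σⱼ Xⱼ cos ω(tⱼ−τ))² / Σⱼ cos² ω(tⱼ−τ)
             + (Σⱼ Xⱼ sin ω(tⱼ−τ))² / Σⱼ sin² ω(tⱼ−τ) ],
    tan 2ωτ = Σⱼ sin 2ωtⱼ / Σⱼ cos 2ωtⱼ,

    variance-normalised so band powers partition the interval variance;
  * nonlinear — Poincaré SD1 = stddev((NNᵢ₊₁ − NNᵢ)/√2),
    SD2 = stddev((NNᵢ₊₁ + NNᵢ)/√2), and SD1/SD2.
* **Cohort statistics** — per-cohort mean±SD tables, pooled-variance
  Student's t-tests (α = 0.05, no multiple-testing correction), and
  cross-modality Pearson correlations with ρ > 0.7 read as strong.
* **A synthetic cardio-mechanical signal generator** with per-beat
  ground truth (controllable mean RR, LF/HF oscillations, noise, AO
  latency and jitter), so the whole pipeline is testable without
  clinical recordings.
* **Text I/O** — a 7-column delimited recording dialect
  (`ecg scg_x scg_y scg_z gcg_x gcg_y gcg_z`, optional `# fs=` header,
  first-sample-artifact discard flag) plus CSV tachograms, annotations
  and result tables. Sampling rates (e.g. 256/512/800 Hz) are carried
  per recording, never resampled.

## Worked example

```python
from cardiohrv import (pan_tompkins, detect_ao, ibi_from_annotations,
                       compute_all)
from cardiohrv.synthetic import SyntheticConfig, generate_recording

cfg = SyntheticConfig(n_beats=360, mean_rr=950, fs=800, seed=42)
rec, truth, _ = generate_recording(cfg)

r = pan_tompkins(rec["ecg"])                      # R waves from the ECG
ao = detect_ao(rec["scg_z"], r, window_ms=100)    # AO waves from the SCG
print(f"R waves: {r.n_beats}, AO waves: {ao.n_beats}")

idx = compute_all(ibi_from_annotations(ao))       # SCG-derived indices
print(idx.as_series().round(4).to_string())
```

prints

```
R waves: 360, AO waves: 360
AVNN        947.3189
SDNN         87.0102
RMSSD       101.8368
pNN50         0.6425
VLF         216.8027
LF         3634.0262
HF         3714.8018
LF/HF         0.9783
SD1          72.1103
SD2          99.9081
SD1/SD2       0.7218
```

AVNN recovers the configured 950 ms mean interval; SDNN ≈ 87 ms matches
the configured rhythm amplitudes and noise (√((75²+65²)/2 + 55²) ≈ 89);
LF/HF ≈ 1 reflects the near-equal LF and HF tone amplitudes; and
SD1 ≈ RMSSD/√2, as it should. VLF is small by construction — the
generator has no 1/f component (see `docs/methods.md`).

The same flow is available from the shell:

```sh
cardiohrv simulate --n-beats 360 --seed 42 --out rec.txt
cardiohrv detect --input rec.txt --modality scg --out ann.csv
cardiohrv hrv --ibi ann.ibi.csv --out indices.csv
cardiohrv run-all --seed 1 --out-dir results/   # full two-cohort experiment
```

`run-all` simulates a 29-subject healthy-like cohort and a 30-subject
VHD-like cohort (larger short-term variability), runs detection and all
indices per modality, and writes six tables — per-modality mean±SD,
t-tests (h, p), and ECG–SCG / ECG–GCG correlations — plus per-subject
tachogram CSVs and a provenance record that makes the run byte-for-byte
reproducible from its seed.

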
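"""Beat detection: Pan–Tompkins R waves in ECG, AO waves in SCG/GCG.

The mechanical beat fiducial is the aortic-valve-opening (AO) wave, a
single sharp peak on the SCG z axis and GCG y axis that follows each R
wave within roughly 100 ms.  Detection is therefore ECG-anchored: first
the R waves, then the AO as the local maximum of the mechanical channel
in a short window after each R, then interval series per modality.

Pan–Tompkins is implemented in its classic form with constants scaled to
the sampling rate: ~5–15 Hz band-pass, five-point derivative, squaring,
150 ms moving-window integration, dual adaptive thresholds with
search-back at half threshold, a 200 ms refractory period and 360 ms
T-wave discrimination.  Filtering is zero-phase, so no group-delay
compensation is needed; each detection is finally refined to the local
maximum of the raw ECG within ±40 ms.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .signals import BeatAnnotations, IBISeries, SampledSignal

REFRACTORY_S = 0.200
TWAVE_WINDOW_S = 0.360
INTEGRATION_S = 0.150
REFINE_S = 0.040
AO_CHANNELS = ("scg_z", "gcg_y")


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def pan_tompkins(ecg: SampledSignal, refine_ms: float = 40.0) -> BeatAnnotations:
    """Detect R waves with the Pan–Tompkins algorithm.

    Returns annotations refined to the local maximum of the raw ECG
    within ``±refine_ms`` of each integrator-stage detection, with no two
    peaks closer than the 200 ms refractory period.  A signal with no
    detections yields an empty annotation and a warning.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValidationError(f"Pan–Tompkins requires fs >= 100 Hz, got {fs}")
    if ecg.duration_s < 5.0:
        raise ValidationError(
            f"signal too short for detection: {ecg.duration_s:.2f} s < 5 s"
        )
    x = np.asarray(ecg.samples, dtype=float)

    bp = _bandpass(x, fs, 5.0, 15.0)
    # centered five-point derivative (antisymmetric kernel, zero delay)
    der = np.convolve(bp, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0), "same")
    sq = der * der
    win = max(1, int(round(INTEGRATION_S * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, "same")

    dist = max(1, int(round(REFRACTORY_S * fs)))
    peaks, _ = sps.find_peaks(mwi, distance=dist)
    if peaks.size == 0:
        warnings.warn("no candidate peaks found; returning empty annotation")
        return BeatAnnotations(modality="ecg", indices=np.array([], dtype=np.int64), fs=fs)

    # threshold learning phase: first 2 s of the integrated signal
    learn = mwi[: int(round(2.0 * fs))]
    spki = 0.5 * float(np.max(learn)) if learn.size else float(mwi[peaks[0]])
    npki = 0.5 * float(np.mean(learn)) if learn.size else 0.0
    thr = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_recent: list[float] = []
    heights = mwi[peaks]

    def slope(p: int) -> float:
        lo = max(0, p - win)
        return float(np.max(np.abs(der[lo: p + 1]))) if p > lo else abs(der[p])

    for j, p in enumerate(peaks):
        h = heights[j]
        if h > thr:
            is_twave = False
            if accepted and (p - accepted[-1]) / fs < TWAVE_WINDOW_S:
                if slope(p) < 0.5 * slope(accepted[-1]):
                    is_twave = True
            if is_twave:
                npki = 0.125 * h + 0.875 * npki
            else:
                if accepted:
                    rr_recent.append((p - accepted[-1]) / fs)
                    del rr_recent[:-8]
                accepted.append(int(p))
                spki = 0.125 * h + 0.875 * spki
        else:
            npki = 0.125 * h + 0.875 * npki
            # search-back: a long gap at half threshold
            if accepted and rr_recent:
                gap = (p - accepted[-1]) / fs
                if gap > 1.66 * float(np.mean(rr_recent)) and h > 0.5 * thr:
                    rr_recent.append(gap)
                    del rr_recent[:-8]
                    accepted.append(int(p))
                    spki = 0.25 * h + 0.75 * spki
        thr = npki + 0.25 * (spki - npki)

    if not accepted:
        warnings.warn("no R waves passed the adaptive threshold")
        return BeatAnnotations(modality="ecg", indices=np.array([], dtype=np.int64), fs=fs)

    # refine to the raw-ECG local maximum within ±refine_ms
    w = max(1, int(round(refine_ms / 1000.0 * fs)))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - w), min(x.size, p + w + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))

    # enforce refractory on the refined indices (earlier peak wins)
    kept: list[int] = []
    for r in refined:
        if not kept or r - kept[-1] >= dist:
            kept.append(int(r))
    return BeatAnnotations(modality="ecg", indices=np.asarray(kept, dtype=np.int64), fs=fs)


def detect_ao(
    mech: SampledSignal,
    r: BeatAnnotations,
    window_ms: float = 100.0,
    symmetric: bool = False,
    prefilter: bool = True,
) -> BeatAnnotations:
    """Locate the AO wave near each R wave in an SCG/GCG channel.

    For each R at index ``k`` the AO is the maximum of the (optionally
    1–30 Hz zero-phase band-passed) channel in the half-open window
    ``[k, k + window)`` — forward-only, since AO physiologically follows
    R — or ``[k - window, k + window)`` with ``symmetric=True``.  Ties go
    to the earliest sample.  Beats whose window runs past the end of the
    signal are dropped.  The result is invariant to positive affine
    rescaling of the channel.
    """
    if mech.label not in AO_CHANNELS:
        raise ValidationError(
            f"AO detection expects one of {AO_CHANNELS}, got {mech.label!r}"
        )
    if mech.fs != r.fs:
        raise ValidationError(f"fs mismatch: channel {mech.fs} Hz vs annotations {r.fs} Hz")
    if window_ms <= 0:
        raise ValidationError(f"window_ms must be positive, got {window_ms}")
    if r.n_beats == 0:
        raise ValidationError("R annotations are empty")

    y = np.asarray(mech.samples, dtype=float)
    if prefilter:
        y = _bandpass(y, mech.fs, 1.0, 30.0)
    n_win = max(1, int(round(window_ms / 1000.0 * mech.fs)))

    ao: list[int] = []
    for k in r.indices:
        lo = k - n_win if symmetric else k
        hi = k + n_win
        if lo < 0 or hi > y.size:
            continue  # window exceeds the signal: drop this beat
        ao.append(int(lo + np.argmax(y[lo:hi])))
    ao_arr = np.asarray(ao, dtype=np.int64)
    # guard against non-monotone picks when windows overlap
    if ao_arr.size > 1:
        keep = np.concatenate([[True], np.diff(ao_arr) > 0])
        ao_arr = ao_arr[keep]
    modality = "scg" if mech.label.startswith("scg") else "gcg"
    return BeatAnnotations(modality=modality, indices=ao_arr, fs=mech.fs)


def ibi_from_annotations(ann: BeatAnnotations) -> IBISeries:
    """Consecutive-beat intervals from annotations.

    ``intervals[i] = (times[i+1] - times[i]) * 1000`` ms and
    ``beat_times[i] = times[i+1]`` (the beat terminating the interval).
    Requires at least 3 annotated beats.
    """
    if ann.n_beats < 3:
        raise ValidationError(
            f"need at least 3 annotated beats to form an IBI series, got {ann.n_beats}"
        )
    # intervals from index differences (not differences of times): a
    # constant sample offset between modalities then cancels exactly
    intervals = np.diff(ann.indices) / ann.fs * 1000.0
    return IBISeries(
        intervals=intervals,
        beat_times=ann.times[1:],
        modality=ann.modality,
    )
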
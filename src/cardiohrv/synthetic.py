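"""Synthetic cardio-mechanical recordings with known beat ground truth.

The generator produces the minimal physiology needed to exercise the
pipeline: an RR-interval process with a controllable mean, Gaussian
beat-to-beat noise and two sinusoidal rhythms (a low-frequency,
baroreflex-like oscillation and a high-frequency, respiration-like one),
rendered into an ECG with one sharp R spike per beat and into SCG/GCG
channels with one aortic-valve-opening (AO) bump per beat at a fixed
latency after R.  Morphological realism (P/T waves, respiration coupling,
disease-specific waveform changes, motion artifacts) is deliberately out
of scope: only fiducial timing matters downstream.

Every draw is driven by a single integer seed through independent
``numpy`` bit-generator streams, so identical configs give bit-identical
arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidConfigError, OverlapError
from .signals import BeatAnnotations, IBISeries, Recording, SampledSignal

# template widths (full width, seconds); only timing matters downstream
_R_WIDTH_S = 0.020
_AO_WIDTH_S = 0.030
# flat lead-in/lead-out around the beat train so edge beats are renderable
_PAD_S = 0.4


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic RR process and its signal rendering.

    Parameters
    ----------
    n_beats : int
        Number of beats; the RR series has ``n_beats - 1`` intervals.
    mean_rr : float
        Mean inter-beat interval, ms.
    rr_noise_sd : float
        SD of the white Gaussian beat-to-beat noise, ms.
    lf_amp, lf_freq : float
        Amplitude (ms) and frequency (Hz) of the low-frequency RR rhythm.
    hf_amp, hf_freq : float
        Amplitude (ms) and frequency (Hz) of the high-frequency RR rhythm.
    fs : float
        Sampling rate of the rendered channels, Hz.
    ao_latency : float
        R-to-AO delay, ms.
    ao_jitter_sd : float
        SD of the per-beat Gaussian jitter on the AO latency, ms;
        truncated at ±3 SD so the AO wave stays inside the search window.
    channel_noise_sd : float
        SD of the additive white noise on every rendered channel,
        in template-amplitude units (templates peak at 1.0).
    seed : int
        Master seed; all randomness derives from it.
    """

    n_beats: int = 300
    mean_rr: float = 950.0
    rr_noise_sd: float = 55.0
    lf_amp: float = 75.0
    lf_freq: float = 0.1
    hf_amp: float = 65.0
    hf_freq: float = 0.25
    fs: float = 800.0
    ao_latency: float = 40.0
    ao_jitter_sd: float = 0.0
    channel_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            "mean_rr": self.mean_rr,
            "rr_noise_sd": self.rr_noise_sd,
            "lf_amp": self.lf_amp,
            "lf_freq": self.lf_freq,
            "hf_amp": self.hf_amp,
            "hf_freq": self.hf_freq,
            "fs": self.fs,
            "ao_latency": self.ao_latency,
            "ao_jitter_sd": self.ao_jitter_sd,
            "channel_noise_sd": self.channel_noise_sd,
        }
        for name, v in numeric.items():
            if not math.isfinite(v):
                raise InvalidConfigError(f"{name} must be finite, got {v}")
        if self.n_beats < 2:
            raise InvalidConfigError(f"n_beats must be >= 2, got {self.n_beats}")
        if self.mean_rr <= 0:
            raise InvalidConfigError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.fs <= 0:
            raise InvalidConfigError(f"fs must be > 0, got {self.fs}")
        if self.ao_latency < 0:
            raise InvalidConfigError(f"ao_latency must be >= 0, got {self.ao_latency}")
        if not self.lf_freq < self.hf_freq:
            raise InvalidConfigError("lf_freq must be below hf_freq")
        for name in ("rr_noise_sd", "lf_amp", "hf_amp", "ao_jitter_sd",
                     "channel_noise_sd", "lf_freq", "hf_freq"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    """Independent generator for one named stream of a config's seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def generate_rr_series(config: SyntheticConfig) -> IBISeries:
    """Generate the RR (inter-beat interval) process of a config.

    Interval *i* is evaluated at the cumulative time of the beat that opens
    it (event sampling, as in a real tachogram)::

        RR_i = mean_rr + lf_amp sin(2π lf_freq t_i)
                       + hf_amp sin(2π hf_freq t_i) + ε_i

    with ``ε_i ~ N(0, rr_noise_sd²)``; intervals are clamped to stay
    positive.  Returns ``n_beats - 1`` intervals with the first beat at
    time 0.
    """
    config.validate()
    n = config.n_beats - 1
    noise = _rng(config, 0).normal(0.0, config.rr_noise_sd, size=n) \
        if config.rr_noise_sd > 0 else np.zeros(n)
    two_pi_lf = 2.0 * math.pi * config.lf_freq
    two_pi_hf = 2.0 * math.pi * config.hf_freq
    intervals = np.empty(n)
    t = 0.0  # s, time of the beat opening the current interval
    for i in range(n):
        rr = (config.mean_rr
              + config.lf_amp * math.sin(two_pi_lf * t)
              + config.hf_amp * math.sin(two_pi_hf * t)
              + noise[i])
        rr = max(rr, 1.0)
        intervals[i] = rr
        t += rr / 1000.0
    beat_times = np.cumsum(intervals) / 1000.0
    return IBISeries(intervals=intervals, beat_times=beat_times, modality="ecg")


def _gauss_template(fs: float, width_s: float) -> np.ndarray:
    """Unit-amplitude Gaussian bump; ``width_s`` is the ±2σ support."""
    sigma = width_s / 4.0
    half = max(1, int(round(3 * sigma * fs)))
    k = np.arange(-half, half + 1)
    return np.exp(-0.5 * (k / (sigma * fs)) ** 2)


def _add_template(signal: np.ndarray, centers: np.ndarray, tpl: np.ndarray) -> None:
    half = (tpl.size - 1) // 2
    n = signal.size
    for c in centers:
        lo, hi = c - half, c + half + 1
        tlo = max(0, -lo)
        thi = tpl.size - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if lo < hi:
            signal[lo:hi] += tpl[tlo:thi]


def render_recording(
    config: SyntheticConfig,
    rr: IBISeries,
    subject_id: str = "synthetic",
    cohort: str = "healthy",
) -> tuple[Recording, dict[str, BeatAnnotations]]:
    """Render an RR series into ECG/SCG/GCG channels with ground truth.

    The ECG gets one narrow spike per beat at the beat time; the SCG z
    axis and GCG y axis get one AO bump per beat at
    ``R + ao_latency + jitter``; the remaining four axes carry only noise.
    Returns the recording and per-modality ground-truth annotations
    (``ecg`` holds R sample indices, ``scg``/``gcg`` the AO indices).
    """
    config.validate()
    if config.fs * config.mean_rr / 1000.0 < 10:
        raise InvalidConfigError("fewer than 10 samples per beat: raise fs or mean_rr")
    min_rr = float(np.min(rr.intervals))
    if config.ao_latency + 3.0 * config.ao_jitter_sd >= min_rr:
        raise OverlapError(
            f"ao_latency + 3*jitter_sd = "
            f"{config.ao_latency + 3 * config.ao_jitter_sd:.1f} ms reaches the "
            f"shortest RR interval ({min_rr:.1f} ms)"
        )

    fs = config.fs
    r_times = _PAD_S + np.concatenate([[0.0], rr.beat_times])
    r_idx = np.round(r_times * fs).astype(np.int64)

    jitter_rng = _rng(config, 1)
    if config.ao_jitter_sd > 0:
        jitter = jitter_rng.normal(0.0, config.ao_jitter_sd, size=r_idx.size)
        lim = 3.0 * config.ao_jitter_sd
        jitter = np.clip(jitter, -lim, lim)
    else:
        jitter = np.zeros(r_idx.size)
    ao_idx = r_idx + np.round((config.ao_latency + jitter) / 1000.0 * fs).astype(np.int64)

    n = int(math.ceil((r_times[-1] + config.ao_latency / 1000.0 + _PAD_S) * fs))
    ecg = np.zeros(n)
    scg_z = np.zeros(n)
    gcg_y = np.zeros(n)
    _add_template(ecg, r_idx, _gauss_template(fs, _R_WIDTH_S))
    ao_tpl = _gauss_template(fs, _AO_WIDTH_S)
    _add_template(scg_z, ao_idx, ao_tpl)
    _add_template(gcg_y, ao_idx, ao_tpl)

    noise_rng = _rng(config, 2)
    data = {"ecg": ecg, "scg_z": scg_z, "gcg_y": gcg_y,
            "scg_x": np.zeros(n), "scg_y": np.zeros(n),
            "gcg_x": np.zeros(n), "gcg_z": np.zeros(n)}
    if config.channel_noise_sd > 0:
        for name in ("ecg", "scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z"):
            data[name] = data[name] + noise_rng.normal(
                0.0, config.channel_noise_sd, size=n)

    channels = {name: SampledSignal(arr, fs=fs, label=name)
                for name, arr in data.items()}
    rec = Recording(channels=channels, subject_id=subject_id, cohort=cohort,
                    dataset_id="synthetic")
    ann = {
        "ecg": BeatAnnotations(modality="ecg", indices=r_idx, fs=fs),
        "scg": BeatAnnotations(modality="scg", indices=ao_idx, fs=fs),
        "gcg": BeatAnnotations(modality="gcg", indices=ao_idx, fs=fs),
    }
    return rec, ann


def generate_recording(
    config: SyntheticConfig,
    subject_id: str = "synthetic",
    cohort: str = "healthy",
) -> tuple[Recording, dict[str, BeatAnnotations], IBISeries]:
    """Convenience: RR series plus rendered recording in one call."""
    rr = generate_rr_series(config)
    rec, ann = render_recording(config, rr, subject_id=subject_id, cohort=cohort)
    return rec, ann, rr


def config_for_duration(config: SyntheticConfig, duration_s: float) -> SyntheticConfig:
    """Return a copy of ``config`` with ``n_beats`` chosen so the beat train
    spans at least ``duration_s`` seconds at the configured mean RR."""
    n_beats = int(math.ceil(duration_s * 1000.0 / config.mean_rr)) + 2
    return replace(config, n_beats=max(n_beats, 2))
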
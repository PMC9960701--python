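"""Core containers: sampled channels, multi-channel recordings, beat
annotations and inter-beat-interval (IBI) series.

Conventions
-----------
* Sample indices are 0-based; beat times are seconds; intervals are ms.
* Sensor axes follow the convention of chest-mounted IMUs: x lateral
  (left→right), y longitudinal (head→foot), z dorsoventral (back→chest).
  The aortic-valve-opening (AO) wave is most prominent on the SCG z axis
  and the GCG y axis, which is why those two channels are mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CHANNEL_LABELS = ("ecg", "scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z")
MODALITIES = ("ecg", "scg", "gcg")
REQUIRED_CHANNELS = ("ecg",)
FIDUCIAL_CHANNELS = ("ecg", "scg_z", "gcg_y")
COHORTS = ("healthy", "vhd")


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : array of float
        Signal values; ECG in mV-scale arbitrary units, SCG in m/s² or raw
        counts, GCG in deg/s or raw counts. Amplitude scale is never
        interpreted downstream.
    fs : float
        Sampling frequency in Hz.
    label : str
        One of ``ecg, scg_x, scg_y, scg_z, gcg_x, gcg_y, gcg_z``.
    """

    samples: np.ndarray
    fs: float
    label: str

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"fs must be positive and finite, got {self.fs}")
        if self.label not in CHANNEL_LABELS:
            raise ValidationError(
                f"label must be one of {CHANNEL_LABELS}, got {self.label!r}"
            )
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("samples must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValidationError(f"non-finite samples in channel {self.label!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Recording:
    """Aligned multi-channel recording for one subject.

    All channels share the sampling rate and length.  The ECG channel is
    mandatory (beat detection is ECG-anchored); a missing ``scg_z`` or
    ``gcg_y`` fiducial channel leaves an explicit gap for that modality
    downstream rather than failing construction.
    """

    channels: dict[str, SampledSignal]
    subject_id: str = ""
    cohort: str = "healthy"
    dataset_id: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ValidationError("recording has no channels")
        for name, ch in self.channels.items():
            if name != ch.label:
                raise ValidationError(f"channel key {name!r} != label {ch.label!r}")
        fss = {ch.fs for ch in self.channels.values()}
        lens = {ch.n_samples for ch in self.channels.values()}
        if len(fss) != 1 or len(lens) != 1:
            raise ValidationError("channels must share fs and sample count")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise ValidationError(f"recording is missing required channels {missing}")
        if self.cohort not in COHORTS:
            raise ValidationError(f"cohort must be one of {COHORTS}")

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __getitem__(self, label: str) -> SampledSignal:
        return self.channels[label]


@dataclass(frozen=True)
class BeatAnnotations:
    """Per-modality beat fiducial positions (R waves or AO waves).

    ``indices`` are 0-based sample indices, strictly increasing; ``times``
    are derived as ``indices / fs``.
    """

    modality: str
    indices: np.ndarray
    fs: float

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError("fs must be positive and finite")
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValidationError("annotation indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValidationError("annotation indices must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    @property
    def n_beats(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class IBISeries:
    """Inter-beat intervals (ms) paired with beat occurrence times (s).

    ``beat_times[i]`` is the time of the beat *terminating* interval
    ``intervals[i]``, so both vectors have the same length N for N+1 beats.
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    modality: str = "ecg"

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "beat_times", bt)
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")
        if iv.shape != bt.shape or iv.ndim != 1:
            raise ValidationError("intervals and beat_times must be 1-D, same length")
        if not np.all(np.isfinite(iv)) or not np.all(np.isfinite(bt)):
            raise ValidationError("non-finite intervals or beat times")
        if np.any(iv <= 0):
            raise ValidationError("all intervals must be positive")
        if iv.size > 1 and np.any(np.diff(bt) <= 0):
            raise ValidationError("beat times must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        """Span from the first to the last annotated beat, in seconds."""
        if self.intervals.size == 0:
            return 0.0
        start = self.beat_times[0] - self.intervals[0] / 1000.0
        return float(self.beat_times[-1] - start)
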
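"""The 11 HRV indices: time domain, Lomb-periodogram frequency domain,
and Poincaré nonlinear geometry.

Time domain
-----------
AVNN (mean NN interval, ms), SDNN (sample SD, ms), RMSSD (root mean
square of successive differences, ms) and pNN50 (fraction of successive
differences strictly greater than 50 ms).

Frequency domain
----------------
Band powers of the NN tachogram in the very-low (0.0033–0.04 Hz), low
(0.04–0.15 Hz) and high (0.15–0.4 Hz) frequency bands, in ms², plus
LF/HF.  The spectrum is a Lomb periodogram, the least-squares estimator
for unevenly sampled series — chosen precisely so the intervals never
need resampling onto a uniform grid::

    P(ω) = 1/2 [ (Σ_j X_j cos ω(t_j − τ))² / Σ_j cos² ω(t_j − τ)
               + (Σ_j X_j sin ω(t_j − τ))² / Σ_j sin² ω(t_j − τ) ]

with the phase origin τ per frequency given by
``tan 2ωτ = Σ_j sin 2ωt_j / Σ_j cos 2ωt_j``; X_j are the mean-subtracted
intervals at beat times t_j.  The raw periodogram is rescaled so that its
Riemann sum over the evaluated grid equals the sample variance of the
intervals, which puts band powers on the conventional ms² scale
(band powers then partition the variance captured below f_max).

Nonlinear
---------
Poincaré SD1/SD2: the scatter of each interval against the next is
projected onto the line perpendicular to the identity line (SD1, the
ellipse width — short-term variability) and onto the identity line
(SD2, the ellipse length — long-term variability).  All SDs use the
sample (N−1) divisor, consistently with SDNN; SD1 then equals RMSSD/√2
only asymptotically, not identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signals import IBISeries

#: Canonical row order for index tables.
INDEX_NAMES = (
    "AVNN", "SDNN", "RMSSD", "pNN50",
    "VLF", "LF", "HF", "LF/HF",
    "SD1", "SD2", "SD1/SD2",
)

PNN_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class BandDefinition:
    """HRV frequency bands (Hz): contiguous, non-overlapping, increasing.

    Band membership downstream is half-open, ``low <= f < high``.
    """

    vlf: tuple[float, float] = (0.0033, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self):
        edges = [*self.vlf, *self.lf, *self.hf]
        if any(e <= 0 for e in edges):
            raise ValidationError("band edges must be positive")
        if not (self.vlf[0] < self.vlf[1] == self.lf[0] < self.lf[1] == self.hf[0] < self.hf[1]):
            raise ValidationError("bands must be contiguous, non-overlapping, increasing")

    @property
    def f_min(self) -> float:
        return self.vlf[0]

    @property
    def f_max(self) -> float:
        return self.hf[1]


@dataclass(frozen=True)
class SpectralEstimate:
    """Frequency grid (Hz) with power density (ms²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    n_freqs: int = 1024

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)
        if f.shape != p.shape or f.ndim != 1:
            raise ValidationError("freqs and power must be 1-D, same length")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValidationError("freqs must be positive, strictly increasing")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValidationError("power must be finite and non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


class TimeDomainIndices(NamedTuple):
    avnn: float
    sdnn: float
    rmssd: float
    pnn50: float


class BandPowers(NamedTuple):
    vlf: float
    lf: float
    hf: float
    lf_hf: float


class PoincareIndices(NamedTuple):
    sd1: float
    sd2: float
    sd1_sd2: float


@dataclass(frozen=True)
class HRVIndices:
    """The 11 indices for one subject/modality."""

    avnn: float
    sdnn: float
    rmssd: float
    pnn50: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float
    sd1: float
    sd2: float
    sd1_sd2: float

    def as_series(self) -> pd.Series:
        """Pandas Series indexed by the canonical table row names."""
        return pd.Series(
            [self.avnn, self.sdnn, self.rmssd, self.pnn50,
             self.vlf, self.lf, self.hf, self.lf_hf,
             self.sd1, self.sd2, self.sd1_sd2],
            index=list(INDEX_NAMES),
        )


def time_domain(series: IBISeries) -> TimeDomainIndices:
    """AVNN, SDNN, RMSSD, pNN50 of an NN-interval series.

    Requires at least 3 intervals (2 successive differences).  pNN50
    counts |ΔNN| *strictly* greater than 50 ms.
    """
    nn = series.intervals
    if nn.size < 3:
        raise ValidationError(f"need >= 3 intervals, got {nn.size}")
    diffs = np.diff(nn)
    return TimeDomainIndices(
        avnn=float(np.mean(nn)),
        sdnn=float(np.std(nn, ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs ** 2))),
        pnn50=float(np.count_nonzero(np.abs(diffs) > PNN_THRESHOLD_MS) / diffs.size),
    )


def lomb_periodogram(
    series: IBISeries,
    n_freqs: int = 1024,
    f_max: float = 0.4,
    min_freq: float | None = 0.0033,
) -> SpectralEstimate:
    """Lomb periodogram of the mean-subtracted tachogram.

    Evaluated at ``n_freqs`` evenly spaced frequencies on ``(0, f_max]``
    and rescaled so the Riemann sum of ``power * df`` equals the sample
    variance of the intervals (ms² normalization).  ``min_freq`` guards
    the lowest band of interest: the series must span more than one cycle
    of it.  Pass ``min_freq=None`` to skip the duration check.
    """
    nn = series.intervals
    t = series.beat_times
    if nn.size < 10:
        raise ValidationError(f"need >= 10 intervals for a spectrum, got {nn.size}")
    if min_freq is not None:
        need = 1.0 / min_freq
        span = float(t[-1] - t[0])
        if span <= need:
            raise ValidationError(
                f"series spans {span:.1f} s but the {min_freq} Hz floor needs "
                f"more than {need:.1f} s"
            )
    x = nn - np.mean(nn)
    freqs = f_max * np.arange(1, n_freqs + 1) / n_freqs
    omega = 2.0 * math.pi * freqs[:, None]          # (F, 1)
    wt = omega * t[None, :]                          # (F, N)
    tau = np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1)) / (
        2.0 * omega[:, 0]
    )
    arg = wt - omega * tau[:, None]
    c = np.cos(arg)
    s = np.sin(arg)
    power = 0.5 * (
        (c @ x) ** 2 / np.einsum("ij,ij->i", c, c)
        + (s @ x) ** 2 / np.einsum("ij,ij->i", s, s)
    )
    power = np.maximum(power, 0.0)

    var = float(np.var(x, ddof=1))
    df = f_max / n_freqs
    total = float(power.sum() * df)
    if total > 0 and var > 0:
        power = power * (var / total)
    else:
        power = np.zeros_like(power)
    return SpectralEstimate(freqs=freqs, power=power, n_freqs=n_freqs)


def band_powers(spec: SpectralEstimate, bands: BandDefinition = BandDefinition()) -> BandPowers:
    """Integrate the spectrum over the VLF/LF/HF bands (half-open bins).

    ``lf_hf`` is NaN when the HF power is zero, never an exception.
    """
    if spec.freqs[0] > bands.f_min or spec.freqs[-1] < bands.f_max - 1e-12:
        raise ValidationError(
            f"spectrum [{spec.freqs[0]:.4g}, {spec.freqs[-1]:.4g}] Hz does not "
            f"cover [{bands.f_min}, {bands.f_max}] Hz"
        )
    df = spec.df

    def integrate(low: float, high: float) -> float:
        mask = (spec.freqs >= low) & (spec.freqs < high)
        return float(spec.power[mask].sum() * df)

    vlf = integrate(*bands.vlf)
    lf = integrate(*bands.lf)
    hf = integrate(*bands.hf)
    lf_hf = lf / hf if hf > 0 else math.nan
    return BandPowers(vlf=vlf, lf=lf, hf=hf, lf_hf=lf_hf)


def poincare(series: IBISeries) -> PoincareIndices:
    """Poincaré SD1/SD2 from the (NN_i, NN_{i+1}) scatter.

    SD1 is the sample SD of ``(NN_{i+1} - NN_i)/√2`` (distance from the
    identity line); SD2 the sample SD of ``(NN_i + NN_{i+1})/√2``
    (spread along the identity line).  The ratio is NaN when SD2 is zero.
    """
    nn = series.intervals
    if nn.size < 3:
        raise ValidationError(f"need >= 3 intervals, got {nn.size}")
    d = (nn[1:] - nn[:-1]) / math.sqrt(2.0)
    ssum = (nn[1:] + nn[:-1]) / math.sqrt(2.0)
    sd1 = float(np.std(d, ddof=1))
    sd2 = float(np.std(ssum, ddof=1))
    return PoincareIndices(
        sd1=sd1, sd2=sd2, sd1_sd2=sd1 / sd2 if sd2 > 0 else math.nan
    )


def compute_all(
    series: IBISeries,
    bands: BandDefinition = BandDefinition(),
    n_freqs: int = 1024,
) -> HRVIndices:
    """All 11 indices for one IBI series with the default band layout."""
    td = time_domain(series)
    spec = lomb_periodogram(
        series, n_freqs=n_freqs, f_max=bands.f_max, min_freq=bands.f_min
    )
    bp = band_powers(spec, bands)
    pc = poincare(series)
    return HRVIndices(
        avnn=td.avnn, sdnn=td.sdnn, rmssd=td.rmssd, pnn50=td.pnn50,
        vlf=bp.vlf, lf=bp.lf, hf=bp.hf, lf_hf=bp.lf_hf,
        sd1=pc.sd1, sd2=pc.sd2, sd1_sd2=pc.sd1_sd2,
    )
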
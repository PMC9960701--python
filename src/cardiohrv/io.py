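"""Text I/O for recordings, beat annotations, IBI series and result tables.

The interchange dialect for recordings is one row per sample with seven
numeric columns in fixed order ``ecg scg_x scg_y scg_z gcg_x gcg_y gcg_z``,
whitespace- or comma-delimited, with an optional leading comment line
``# fs=<Hz> ...``.  The healthy-reference datasets in this field ship as
per-subject plain-text files of exactly this shape, some of which carry a
spurious first sample; ``discard_first`` reproduces the convention of
dropping that row.  Sampling-rate heterogeneity across datasets
(256/512/800 Hz) is carried per recording and never resampled.

An explicit ``fs`` argument always takes precedence over a header value.
Units are passed through unscaled: every downstream operation is invariant
to positive rescaling of a channel.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .signals import CHANNEL_LABELS, BeatAnnotations, IBISeries, Recording, SampledSignal

_FS_RE = re.compile(r"fs\s*=\s*([0-9.eE+-]+)")


def read_recording_text(
    path: str | Path,
    fs: float | None = None,
    discard_first: bool = False,
    subject_id: str | None = None,
    cohort: str = "healthy",
    dataset_id: str = "",
) -> Recording:
    """Read a delimited-text recording (7 columns, fixed channel order).

    ``fs`` may come from the ``# fs=...`` header; an explicit argument
    overrides it.  With ``discard_first`` the first sample row is dropped
    from every channel (the first-sample artifact convention).
    """
    path = Path(path)
    header_fs: float | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _FS_RE.search(line)
                if m:
                    header_fs = float(m.group(1))
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != len(CHANNEL_LABELS):
                raise ParseError(
                    f"expected {len(CHANNEL_LABELS)} columns, found {len(fields)}",
                    line=lineno,
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from exc

    eff_fs = fs if fs is not None else header_fs
    if eff_fs is None:
        raise ParseError(f"{path}: no sampling rate in header and none supplied")
    if discard_first and rows:
        rows = rows[1:]
    if len(rows) < 2:
        raise ParseError(
            f"{path}: fewer than 2 sample rows"
            + (" after discarding the first" if discard_first else "")
        )
    data = np.asarray(rows, dtype=float)
    channels = {
        label: SampledSignal(data[:, j], fs=eff_fs, label=label)
        for j, label in enumerate(CHANNEL_LABELS)
    }
    return Recording(
        channels=channels,
        subject_id=subject_id if subject_id is not None else path.stem,
        cohort=cohort,
        dataset_id=dataset_id,
    )


def write_recording_text(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the 7-column dialect at full float precision.

    Channels absent from the recording (only the optional axes can be)
    are written as zero columns so the on-disk shape is always complete.
    """
    path = Path(path)
    if not rec.channels:
        raise ValidationError("recording has no channels")
    n = rec.n_samples
    cols = []
    for label in CHANNEL_LABELS:
        if label in rec.channels:
            cols.append(rec.channels[label].samples)
        else:
            cols.append(np.zeros(n))
    data = np.column_stack(cols)
    header = f"# fs={rec.fs:.17g} columns={','.join(CHANNEL_LABELS)}"
    np.savetxt(path, data, fmt="%.17g", delimiter=" ", header=header, comments="")
    return path


def write_ibi_csv(series: IBISeries, path: str | Path) -> Path:
    """Write an IBI series (tachogram) as two-column CSV
    ``beat_time_s, ibi_ms`` with a modality comment header."""
    path = Path(path)
    df = pd.DataFrame(
        {"beat_time_s": series.beat_times, "ibi_ms": series.intervals}
    )
    with open(path, "w") as fh:
        fh.write(f"# modality={series.modality}\n")
        df.to_csv(fh, index=False, float_format="%.15g")
    return path


def read_ibi_csv(path: str | Path, modality: str | None = None) -> IBISeries:
    path = Path(path)
    header_modality = "ecg"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        m = re.search(r"modality\s*=\s*(\w+)", first)
        if m:
            header_modality = m.group(1)
    df = pd.read_csv(path, comment="#")
    if not {"beat_time_s", "ibi_ms"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns beat_time_s, ibi_ms")
    iv = df["ibi_ms"].to_numpy(dtype=float)
    if np.any(iv <= 0):
        bad = int(np.flatnonzero(iv <= 0)[0])
        raise ValidationError(
            f"{path}: non-positive interval {iv[bad]} ms at row {bad}"
        )
    return IBISeries(
        intervals=iv,
        beat_times=df["beat_time_s"].to_numpy(dtype=float),
        modality=modality if modality is not None else header_modality,
    )


def write_annotations_csv(ann: BeatAnnotations, path: str | Path) -> Path:
    """Write beat annotations as CSV ``modality, sample_index, time_s``."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "modality": ann.modality,
            "sample_index": ann.indices,
            "time_s": ann.times,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# fs={ann.fs:.17g}\n")
        df.to_csv(fh, index=False, float_format="%.15g")
    return path


def read_annotations_csv(path: str | Path, fs: float | None = None) -> BeatAnnotations:
    path = Path(path)
    header_fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        m = _FS_RE.search(first)
        if m:
            header_fs = float(m.group(1))
    eff_fs = fs if fs is not None else header_fs
    if eff_fs is None:
        raise ParseError(f"{path}: no fs in header and none supplied")
    df = pd.read_csv(path, comment="#")
    if not {"modality", "sample_index"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns modality, sample_index")
    modalities = df["modality"].unique()
    if len(modalities) != 1:
        raise ParseError(f"{path}: mixed modalities {list(modalities)}")
    return BeatAnnotations(
        modality=str(modalities[0]),
        indices=df["sample_index"].to_numpy(dtype=np.int64),
        fs=eff_fs,
    )
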
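"""Cohort-level statistics: per-group summary tables, two-sample t-tests
and cross-modality Pearson correlations.

The study design this supports compares HRV indices between a healthy
cohort and a valvular-heart-disease (VHD) cohort, for each of three
modalities (ECG, SCG, GCG), and checks agreement between modalities via
Pearson's ρ with ρ > 0.7 read as a strong linear correlation.  Tests are
classic pooled-variance (Student's) two-sample t-tests at α = 0.05, run
per index with **no multiple-testing correction** — 33 raw tests across
11 indices × 3 modalities, so a handful of rejections is expected under
the global null; interpret single rejections accordingly.  A Welch
option is available for unequal variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError
from .metrics import INDEX_NAMES, HRVIndices

STRONG_RHO = 0.7
MODALITY_ORDER = ("ecg", "scg", "gcg")


@dataclass(frozen=True)
class TestResult:
    """One two-sample t-test; h = 1 iff p < alpha."""

    index_name: str
    t_statistic: float
    p_value: float
    h: int
    alpha: float = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson correlation; ``strong`` applies the ρ > 0.7 rule."""

    index_name: str
    rho: float
    p_value: float
    strong: bool


def indices_frame(per_subject: Sequence[HRVIndices]) -> pd.DataFrame:
    """Subjects × indices DataFrame (columns in canonical order)."""
    return pd.DataFrame([s.as_series() for s in per_subject])


def summarize_cohort(
    per_subject: Sequence[HRVIndices], cohort_label: str
) -> pd.DataFrame:
    """Mean and sample SD of each index across subjects.

    Undefined (NaN) entries are excluded per index with the effective n
    reported; an all-NaN index column yields NaN mean/SD and n = 0.
    Rows follow the canonical index order.
    """
    if len(per_subject) < 2:
        raise ValidationError(f"cohort {cohort_label!r} needs >= 2 subjects")
    df = indices_frame(per_subject)
    out = pd.DataFrame(
        {
            "mean": df.mean(skipna=True),
            "sd": df.std(ddof=1, skipna=True),
            "n": df.notna().sum(),
        },
        index=list(INDEX_NAMES),
    )
    out.index.name = "index"
    out.attrs["cohort"] = cohort_label
    return out


def group_ttest(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    index_name: str = "",
    welch: bool = False,
) -> TestResult:
    """Two-sided two-sample t-test (pooled-variance by default).

    Non-finite values are dropped; each group needs >= 2 finite values.
    A degenerate case with zero variance in both groups gives t = 0,
    p = 1 when the means are equal, and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"t-test needs >= 2 finite values per group, got {a.size} and {b.size}"
        )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, float(np.mean(a) - np.mean(b)))
            p = 0.0
    else:
        t, p = sstats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return TestResult(
        index_name=index_name,
        t_statistic=t,
        p_value=p,
        h=int(p < alpha),
        alpha=alpha,
    )


def pairwise_pearson(
    x: Sequence[float], y: Sequence[float], index_name: str = ""
) -> CorrelationResult:
    """Pearson product-moment correlation of subject-paired values.

    Pairs with an undefined member are dropped; needs >= 3 complete
    pairs.  Zero variance in either vector gives an undefined (NaN) ρ.
    The strong flag applies ρ > 0.7 (one-sided, as the rule is stated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be subject-paired, equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {x.size}")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(index_name, math.nan, math.nan, False)
    if np.array_equal(x, y):
        # element-wise identical vectors correlate exactly; bypass the
        # 1-ulp round-off of the product-moment arithmetic
        return CorrelationResult(index_name, 1.0, 0.0, True)
    r = sstats.pearsonr(x, y)
    rho, p = float(r.statistic), float(r.pvalue)
    return CorrelationResult(
        index_name=index_name, rho=rho, p_value=p, strong=bool(rho > STRONG_RHO)
    )


def ttest_table(
    healthy: dict[str, Sequence[HRVIndices]],
    vhd: dict[str, Sequence[HRVIndices]],
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Healthy-vs-VHD t-tests per index for each available modality.

    Rows: indices in canonical order; columns: ``<modality>_h``,
    ``<modality>_p``.  A modality missing from either cohort yields NaN
    columns (an explicit gap, never imputation).
    """
    cols: dict[str, list[float]] = {}
    for mod in MODALITY_ORDER:
        h_col, p_col = [], []
        have = mod in healthy and mod in vhd
        dfa = indices_frame(healthy[mod]) if have else None
        dfb = indices_frame(vhd[mod]) if have else None
        for name in INDEX_NAMES:
            if not have:
                h_col.append(math.nan)
                p_col.append(math.nan)
                continue
            res = group_ttest(dfa[name], dfb[name], alpha=alpha,
                              index_name=name, welch=welch)
            h_col.append(res.h)
            p_col.append(res.p_value)
        cols[f"{mod}_h"] = h_col
        cols[f"{mod}_p"] = p_col
    out = pd.DataFrame(cols, index=list(INDEX_NAMES))
    out.index.name = "index"
    return out


def correlation_table(
    by_modality: dict[str, Sequence[HRVIndices]],
    reference: str = "ecg",
    other: str = "scg",
) -> pd.DataFrame:
    """Per-index Pearson ρ between two modalities of one cohort."""
    if reference not in by_modality or other not in by_modality:
        raise ValidationError(f"need both {reference!r} and {other!r} modalities")
    dfa = indices_frame(by_modality[reference])
    dfb = indices_frame(by_modality[other])
    rows = []
    for name in INDEX_NAMES:
        res = pairwise_pearson(dfa[name], dfb[name], index_name=name)
        rows.append({"rho": res.rho, "p": res.p_value, "strong": res.strong})
    out = pd.DataFrame(rows, index=list(INDEX_NAMES))
    out.index.name = "index"
    return out


def build_report(
    cohorts: dict[str, dict[str, Sequence[HRVIndices]]],
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> dict[str, pd.DataFrame]:
    """Build the six result tables of the two-cohort, three-modality design.

    ``cohorts`` maps cohort → modality → per-subject indices (subject-
    aligned across modalities within a cohort).  Emits per-modality
    mean±SD tables (one per modality, both cohorts side by side), the
    t-test table, and ECG–SCG / ECG–GCG correlation tables per cohort.
    Missing modalities leave explicit NaN gaps.  When ``out_dir`` is
    given each table is also written as CSV.
    """
    healthy = cohorts.get("healthy", {})
    vhd = cohorts.get("vhd", {})
    tables: dict[str, pd.DataFrame] = {}

    for mod in MODALITY_ORDER:
        parts = []
        for label, grp in (("healthy", healthy), ("vhd", vhd)):
            if mod in grp and len(grp[mod]) >= 2:
                summ = summarize_cohort(grp[mod], label)
            else:
                summ = pd.DataFrame(
                    {"mean": math.nan, "sd": math.nan, "n": 0},
                    index=list(INDEX_NAMES),
                )
            summ = summ.rename(columns={c: f"{label}_{c}" for c in summ.columns})
            parts.append(summ)
        tab = pd.concat(parts, axis=1)
        tab.index.name = "index"
        tables[f"indices_{mod}"] = tab

    tables["ttests"] = ttest_table(healthy, vhd, alpha=alpha, welch=welch)

    for other in ("scg", "gcg"):
        parts = []
        for cohort_label, grp in (("healthy", healthy), ("vhd", vhd)):
            if "ecg" in grp and other in grp and len(grp.get("ecg", [])) >= 3:
                part = correlation_table(grp, "ecg", other)
            else:
                part = pd.DataFrame(
                    {"rho": math.nan, "p": math.nan, "strong": False},
                    index=list(INDEX_NAMES),
                )
            part = part.rename(columns={c: f"{cohort_label}_{c}" for c in part.columns})
            parts.append(part)
        tab = pd.concat(parts, axis=1)
        tab.index.name = "index"
        tables[f"correlation_ecg_{other}"] = tab

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out_dir / f"{name}.csv")
    return tables
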
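"""Condition-level statistics: mean ± SEM, t-tests, fold-changes, TNR.

One data point is one ROI triple; focal-leak-flagged points are excluded
from aggregation by default (they are retained, flagged, in the measurement
table). Comparisons use the two-sample two-tailed Student's t-test with
pooled variance (Welch available as an option), significance at α = 0.05,
with no multiple-testing correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .permeability import PdMeasurement

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "aggregate",
    "ttest",
    "fold_change",
    "compute_tnr",
    "size_selectivity_table",
    "round_sig",
]

ALPHA = 0.05


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report convention for ratios)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class ConditionSummary:
    """Mean ± SEM permeability of one condition/probe combination."""

    condition: str
    probe: str
    n: int
    mean_Pd: float  # cm/s
    sem_Pd: float  # cm/s
    n_excluded: int = 0
    d_H: Optional[float] = None  # hydrodynamic diameter, nm

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a summary needs at least one data point")


@dataclass
class ComparisonResult:
    """Two-sample Student's t-test between conditions, with fold-change."""

    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    significant: bool
    fold_change: float  # mean_a / mean_b
    n_a: int = 0
    n_b: int = 0


def aggregate(
    measurements: Sequence[PdMeasurement],
    condition: str = "",
    probe: str = "",
    exclude_flagged: bool = True,
    d_H: Optional[float] = None,
) -> ConditionSummary:
    """Mean and SEM of P_d over QC-passing measurements.

    Focal-leak-flagged or failed measurements are excluded (reported in
    ``n_excluded``). An n = 1 group reports SEM 0 with a warning rather
    than failing, to keep batch runs alive.
    """
    vals = []
    excluded = 0
    for m in measurements:
        if not m.ok or (exclude_flagged and m.focal_leak) or not math.isfinite(m.P_d):
            excluded += 1
        else:
            vals.append(m.P_d)
    if not vals:
        raise ValueError(f"all {len(measurements)} data points excluded for {condition}/{probe}")
    arr = np.asarray(vals)
    if arr.size == 1:
        warnings.warn(f"single data point for {condition}/{probe}: SEM reported as 0")
        sem = 0.0
    else:
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return ConditionSummary(
        condition=condition,
        probe=probe,
        n=int(arr.size),
        mean_Pd=float(arr.mean()),
        sem_Pd=sem,
        n_excluded=excluded,
        d_H=d_H,
    )


def ttest(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-sample two-tailed t-test on P_d values (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
    if b.mean() == 0:
        raise ValueError("group b has zero mean; fold-change undefined")
    return ComparisonResult(
        group_a=labels[0],
        group_b=labels[1],
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < alpha),
        fold_change=float(a.mean() / b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def fold_change(baseline: ConditionSummary, treated: ConditionSummary, sig: int = 3) -> float:
    """Fold-decrease of P_d from baseline to treated: mean_baseline/mean_treated,
    reported to ``sig`` significant figures."""
    if treated.mean_Pd <= 0:
        raise ValueError("treated mean P_d must be > 0")
    return round_sig(baseline.mean_Pd / treated.mean_Pd, sig)


def compute_tnr(tumor: ConditionSummary, normal: ConditionSummary) -> dict:
    """Tumor-to-normal permeability ratio for one probe.

    TNR = P_d,tumor / P_d,normal, with first-order propagated uncertainty
    ``tnr·√((sem_t/mean_t)² + (sem_n/mean_n)²)`` (the propagation is this
    package's addition; upstream reports give the ratio alone).
    """
    if tumor.probe != normal.probe:
        raise ValueError(f"probe mismatch: {tumor.probe!r} vs {normal.probe!r}")
    if normal.mean_Pd <= 0:
        raise ValueError("normal mean P_d must be > 0")
    tnr = tumor.mean_Pd / normal.mean_Pd
    rel = math.sqrt(
        (tumor.sem_Pd / tumor.mean_Pd) ** 2 + (normal.sem_Pd / normal.mean_Pd) ** 2
    )
    return {
        "probe": tumor.probe,
        "d_H": tumor.d_H,
        "Pd_tumor": tumor.mean_Pd,
        "Pd_normal": normal.mean_Pd,
        "tnr": tnr,
        "tnr_sem": tnr * rel,
    }


def size_selectivity_table(
    summaries: Sequence[ConditionSummary],
    groups: Optional[dict[str, Sequence[float]]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """P_d vs hydrodynamic diameter, sorted by size, with adjacent-size t-tests.

    Parameters
    ----------
    summaries : sequence of ConditionSummary
        One per probe size; each must carry ``d_H``.
    groups : dict, optional
        Raw per-point P_d values keyed by probe label; when given, each
        adjacent pair of sizes gets a t-test (columns ``p_vs_next`` /
        ``significant_vs_next`` on the smaller size's row).
    """
    if len(summaries) < 2:
        raise ValueError("need at least two probe sizes")
    if any(s.d_H is None for s in summaries):
        raise ValueError("every summary needs a hydrodynamic diameter d_H")
    ordered = sorted(summaries, key=lambda s: s.d_H)
    rows = [
        {"probe": s.probe, "d_H_nm": s.d_H, "mean_Pd": s.mean_Pd, "sem_Pd": s.sem_Pd, "n": s.n}
        for s in ordered
    ]
    df = pd.DataFrame(rows)
    df["p_vs_next"] = np.nan
    df["significant_vs_next"] = pd.array([None] * len(df), dtype="boolean")
    if groups is not None:
        for i in range(len(ordered) - 1):
            a, b = ordered[i], ordered[i + 1]
            res = ttest(groups[a.probe], groups[b.probe], labels=(a.probe, b.probe), welch=welch)
            df.loc[i, "p_vs_next"] = res.p_value
            df.loc[i, "significant_vs_next"] = res.significant
    return df
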
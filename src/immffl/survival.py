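"""Kaplan-Meier estimation, expression dichotomization, log-rank test and
Mantel-Haenszel hazard ratio.

Samples are split into low/high expression groups (median split by
default), overall survival is compared with the standard log-rank
chi-square (1 df), and the hazard ratio is the Mantel-Haenszel estimate
(O_low/E_low)/(O_high/E_high), oriented so HR > 1 means worse survival in
the low-expression group.  Tied event times contribute a single 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DichotomizationError, LabelError

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class SurvivalComparison:
    chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    median_low: float | None
    median_high: float | None
    n_low: int
    n_high: int


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    need = {"sample_id", "time_months", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(need)}")
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def dichotomize(expr: pd.Series, method: str = "median") -> pd.Series:
    """Split samples into low/high expression groups.

    ``median``: at or below the sample median -> low.  ``best_cutoff``:
    scan candidate cutpoints between the 25th and 75th percentiles and
    return the labels only; use :func:`best_cutoff_split` when the scan
    needs survival data.
    """
    if expr.size < 4:
        raise DichotomizationError("need >= 4 samples to dichotomize")
    if np.ptp(expr.to_numpy(dtype=float)) == 0:
        raise DichotomizationError("constant expression cannot be split")
    if method != "median":
        raise ValueError("use best_cutoff_split for the best-cutoff method")
    med = expr.median()
    return pd.Series(np.where(expr <= med, LOW, HIGH), index=expr.index)


def best_cutoff_split(
    expr: pd.Series, table: pd.DataFrame
) -> tuple[pd.Series, float, float]:
    """Log-rank-p-minimizing split over cutpoints in the interquartile range.

    Returns (labels, cutoff, p).  The returned p is selection-biased (it is
    the minimum over the scan) and must not be quoted as a test result.
    """
    if expr.size < 4:
        raise DichotomizationError("need >= 4 samples to dichotomize")
    vals = expr.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise DichotomizationError("constant expression cannot be split")
    q25, q75 = np.quantile(vals, [0.25, 0.75])
    candidates = sorted(set(vals[(vals >= q25) & (vals <= q75)]))
    best = None
    for cut in candidates:
        labels = pd.Series(np.where(expr <= cut, LOW, HIGH), index=expr.index)
        if labels.nunique() < 2:
            continue
        merged = table.set_index("sample_id").loc[labels.index]
        merged = merged.assign(group=labels.values)
        try:
            cmp = logrank_hr(merged.reset_index())
        except LabelError:
            continue
        if best is None or cmp.p < best[2]:
            best = (labels, float(cut), cmp.p)
    if best is None:
        raise DichotomizationError("no valid cutpoint in the interquartile range")
    return best


def km_estimate(table: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Product-limit survival curve and median survival time.

    Returns (curve, median) where curve has columns time, n_at_risk,
    n_events, survival and median is the earliest time with S(t) <= 0.5
    (None if S never reaches 0.5).
    """
    if len(table) == 0:
        raise ValueError("empty survival table")
    times = table["time_months"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = len(times)
    at_risk = n
    i = 0
    median = None
    while i < n:
        t = times[i]
        j = i
        d = 0
        c = 0
        while j < n and times[j] == t:
            d += events[j]
            c += 1 - events[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append(
                {"time": t, "n_at_risk": at_risk, "n_events": d, "survival": s}
            )
            if median is None and s <= 0.5:
                median = float(t)
        at_risk -= d + c
        i = j
    curve = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])
    return curve, median


def logrank_hr(table: pd.DataFrame) -> SurvivalComparison:
    """Log-rank chi-square and Mantel-Haenszel HR between low/high groups.

    At each distinct event time a 2x2 table of events vs at-risk counts is
    accumulated; the chi-square uses the hypergeometric variance.  HR is
    (O_low/E_low)/(O_high/E_high) with Wald CI
    exp(log HR +/- 1.96 sqrt(1/E_low + 1/E_high)); a group with zero
    expected events leaves the HR undefined (NaN) while p is still valid.
    """
    if "group" not in table.columns:
        raise LabelError("survival table lacks a 'group' column")
    low = table[table["group"] == LOW]
    high = table[table["group"] == HIGH]
    if len(low) == 0 or len(high) == 0:
        raise LabelError("both low and high groups must be non-empty")
    times = table["time_months"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    is_low = (table["group"] == LOW).to_numpy()

    event_times = np.unique(times[events == 1])
    o_low = e_low = o_high = e_high = v_sum = 0.0
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        n1 = (at_risk & is_low).sum()
        d_t = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & is_low).sum()
        o_low += d1
        o_high += d_t - d1
        e1 = d_t * n1 / n_t
        e_low += e1
        e_high += d_t - e1
        if n_t > 1:
            v_sum += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if v_sum > 0:
        chi2 = (o_low - e_low) ** 2 / v_sum
        p = float(stats.chi2.sf(chi2, 1))
    else:
        chi2, p = 0.0, 1.0
    if e_low > 0 and e_high > 0 and o_low > 0 and o_high > 0:
        hr = (o_low / e_low) / (o_high / e_high)
        half = 1.959963984540054 * np.sqrt(1.0 / e_low + 1.0 / e_high)
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    elif e_low > 0 and e_high > 0:
        hr = (o_low / e_low) / (o_high / e_high) if o_high > 0 else np.nan
        ci = (np.nan, np.nan)
        hr = float(hr) if np.isfinite(hr) else float("nan")
    else:
        hr, ci = float("nan"), (np.nan, np.nan)
    _, med_low = km_estimate(low)
    _, med_high = km_estimate(high)
    return SurvivalComparison(
        chi2=float(chi2),
        p=p,
        hr=float(hr),
        hr_ci=ci,
        median_low=med_low,
        median_high=med_high,
        n_low=int(len(low)),
        n_high=int(len(high)),
    )
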
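"""Moderated two-group differential expression with empirical-Bayes shrinkage.

The engine fits, per feature, the two-group linear model (tumor vs normal)
on log2 expression, pools residual variances across features through a
scaled-F prior fitted by method of moments, and tests the moderated
t-statistic

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df)
    t_mod     = log2fc / (s_tilde * sqrt(1/n1 + 1/n2)),   df_total = df + d0

With d0 = 0 this reduces exactly to the classic pooled two-sample t; with
d0 = +inf every feature is tested against the common prior variance s0^2.
Calls are made at strict thresholds |log2FC| > fc_threshold and
BH-adjusted p < p_threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort, NORMAL, TUMOR
from .errors import ContrastError, ModerationError

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class ModerationParams:
    """Hyperparameters of the scaled-F variance prior.

    d0 is the prior degrees of freedom (``inf`` = full shrinkage to s0_sq),
    s0_sq the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ModerationError("d0 must be >= 0")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ModerationError("s0_sq must be finite and positive")


def fit_group_stats(
    cohort: ExpressionCohort, group_a: str = TUMOR, group_b: str = NORMAL
) -> pd.DataFrame:
    """Per-feature group means, pooled residual variance and residual df.

    Returns a DataFrame indexed by feature with columns ``mean_tumor``,
    ``mean_normal``, ``log2fc`` (tumor minus normal), ``s2``, ``df``,
    ``n1``, ``n2``.
    """
    a_cols = cohort.samples_in_group(group_a)
    b_cols = cohort.samples_in_group(group_b)
    if not a_cols or not b_cols:
        raise ContrastError(
            f"both groups must be non-empty (got {len(a_cols)} '{group_a}', "
            f"{len(b_cols)} '{group_b}')"
        )
    n1, n2 = len(a_cols), len(b_cols)
    df = n1 + n2 - 2
    if df < 1:
        raise ContrastError("residual degrees of freedom < 1")
    a = cohort.values[a_cols].to_numpy(dtype=float)
    b = cohort.values[b_cols].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    rss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / df
    return pd.DataFrame(
        {
            "mean_tumor": mean_a,
            "mean_normal": mean_b,
            "log2fc": mean_a - mean_b,
            "s2": s2,
            "df": float(df),
            "n1": n1,
            "n2": n2,
        },
        index=cohort.values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the scaled-F prior to observed variances.

    Matches mean and variance of log s^2: the excess spread of log s^2
    beyond what the residual chi-square alone implies determines d0; if
    there is no excess spread, d0 = +inf and s0_sq is the mean-based
    estimate.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ModerationError("need >= 2 features with positive variance")
    z = np.log(positive)
    zmean = z.mean()
    zvar = z.var(ddof=1)
    # E/Var of log chi2_df/df
    e_chi = special.digamma(df / 2.0) - math.log(df / 2.0)
    v_chi = float(special.polygamma(1, df / 2.0))
    evar = zvar - v_chi
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        log_s0 = (
            zmean
            - e_chi
            - (math.log(d0 / 2.0) - special.digamma(d0 / 2.0))
        )
    else:
        d0 = math.inf
        log_s0 = zmean - e_chi
    return ModerationParams(d0=float(d0), s0_sq=float(math.exp(log_s0)))


def moderated_t(stats_df: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Moderated t, total df and two-sided p for every feature.

    Returns the input frame with ``s2_post``, ``t_mod``, ``df_total`` and
    ``p`` columns appended.
    """
    if not np.isfinite(stats_df[["log2fc", "s2"]].to_numpy()).all():
        raise ContrastError("non-finite group statistics")
    s2 = stats_df["s2"].to_numpy(dtype=float)
    df = stats_df["df"].to_numpy(dtype=float)
    lfc = stats_df["log2fc"].to_numpy(dtype=float)
    n1 = stats_df["n1"].to_numpy(dtype=float)
    n2 = stats_df["n2"].to_numpy(dtype=float)
    if math.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = np.full_like(s2, math.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        df_total = df + params.d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = np.empty_like(t_mod)
    finite_df = np.isfinite(df_total)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t_mod[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t_mod[~finite_df]))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = stats_df.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p"] = p
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Assign up/down/ns calls at strict |log2FC| and adjusted-p thresholds."""
    if "p_adj" not in table.columns:
        raise ContrastError("adjusted p-values absent; run bh_adjust first")
    lfc = table["log2fc"]
    sig = table["p_adj"] < p_threshold
    call = np.where(
        sig & (lfc > fc_threshold),
        "up",
        np.where(sig & (lfc < -fc_threshold), "down", "ns"),
    )
    out = table.copy()
    out["call"] = call
    return out


def differential_expression(
    cohort: ExpressionCohort,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Full moderated-t pipeline: fit, moderate, adjust, call.

    Returns the DifferentialTable as a DataFrame indexed by feature id with
    columns log2fc, t_mod, df_total, p, p_adj, call (plus fit internals).
    """
    stats_df = fit_group_stats(cohort)
    params = estimate_moderation(stats_df["s2"].to_numpy(), float(stats_df["df"].iloc[0]))
    table = moderated_t(stats_df, params)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return call_differential(table, fc_threshold, p_threshold)
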
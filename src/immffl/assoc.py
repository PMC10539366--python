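"""Diagnostic and association statistics: ROC/AUC, (partial) Spearman,
2^-ddCt relative quantification, and the pooled two-group t.

AUC is the Mann-Whitney statistic with half credit for ties; its 95% CI is
DeLong's asymptotic interval, clamped to [0, 1].  Orientation is never
flipped: an AUC below 0.5 reports a marker higher in the negative class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import LabelError


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    adjusted_for: str | None = None
    covariate_degenerate: bool = False


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive: str = "tumor") -> ROCResult:
    """AUC with DeLong 95% confidence interval.

    ``labels`` holds two class labels; ``positive`` names the class whose
    higher scores count toward AUC > 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise LabelError("both classes must be present for ROC analysis")
    # placement values: V10[i] = P(pos_i beats a random negative), etc.
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = float(psi.mean())
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    half = 1.959963984540054 * np.sqrt(var)
    return ROCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(x.size))


def partial_spearman(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, covariate_name: str = "purity"
) -> CorrelationResult:
    """Rank-based partial correlation of x and y given covariate z.

    All three vectors are rank-transformed, then the partial Pearson
    correlation is computed from residuals of x and y each regressed on z;
    p comes from the t approximation with n - 3 df.  A constant covariate
    degenerates to the plain Spearman correlation, flagged in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size) or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(z) == 0:
        warnings.warn(
            "constant covariate; falling back to unadjusted Spearman",
            RuntimeWarning,
            stacklevel=2,
        )
        plain = spearman(x, y)
        return CorrelationResult(
            rho=plain.rho, p=plain.p, n=plain.n,
            adjusted_for=None, covariate_degenerate=True,
        )
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))

    def _resid(v: np.ndarray, w: np.ndarray) -> np.ndarray:
        v_c, w_c = v - v.mean(), w - w.mean()
        return v_c - w_c * (v_c @ w_c) / (w_c @ w_c)

    ex, ey = _resid(rx, rz), _resid(ry, rz)
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0)) if denom > 0 else 0.0
    n = x.size
    df = n - 3
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tstat = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    return CorrelationResult(rho=rho, p=p, n=int(n), adjusted_for=covariate_name)


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative quantification 2^-ddCt against an endogenous control.

    dCt = Ct(target) - Ct(reference) per condition; ddCt is the treated
    minus control difference of dCt values.
    """
    vals = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct))


def two_group_t(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided pooled-variance Student t; returns (t, p, significant)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, False
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), bool(p < alpha)
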
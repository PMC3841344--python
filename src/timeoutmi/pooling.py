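"""Rubin's rules: combine estimates and standard errors across imputations.

For per-imputation estimates Q_1..Q_M with standard errors W_1..W_M:

    pooled estimate   Qbar = (1/M) * sum_m Q_m
    within variance   Wbar = (1/M) * sum_m W_m^2
    between variance  B    = (1/(M-1)) * sum_m (Q_m - Qbar)^2
    total variance    T^2  = Wbar + (1 + 1/M) * B

Confidence intervals use normal reference quantiles (no small-sample
degrees-of-freedom correction; sample sizes here are large).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PooledEstimate:
    estimates: tuple[float, ...]
    std_errors: tuple[float, ...]
    pooled: float
    within_var: float
    between_var: float
    total_se: float
    m: int
    level: float
    ci_low: float
    ci_high: float

    @property
    def fraction_missing_info(self) -> float:
        """Share of total variance due to imputation, (1+1/M)B / T^2."""
        if self.total_se == 0:
            return 0.0
        return (1 + 1 / self.m) * self.between_var / self.total_se**2


@dataclass(frozen=True)
class PooledRatio:
    """Exp-transformed pooled coefficient for ratio-scale reporting."""

    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    pooled: PooledEstimate


def pool(
    estimates: Sequence[float],
    std_errors: Sequence[float],
    level: float = 0.95,
) -> PooledEstimate:
    """Pool per-imputation estimates and standard errors.

    Requires M >= 2 (between-imputation variance is undefined below
    that) and equal-length inputs with non-negative standard errors.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(std_errors, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and std_errors must have equal length")
    m = q.size
    if m < 2:
        raise ValueError("pooling requires at least two imputations")
    if np.any(w < 0):
        raise ValueError("standard errors must be non-negative")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")

    if np.ptp(q) == 0:  # identical estimates: collapse exactly, no round-off
        qbar = float(q[0])
        between = 0.0
    else:
        qbar = float(q.mean())
        between = float(np.sum((q - qbar) ** 2) / (m - 1))
    wbar = float(np.mean(w**2))
    total_se = math.sqrt(wbar + (1 + 1 / m) * between)
    z = stats.norm.ppf(0.5 + level / 2)
    return PooledEstimate(
        estimates=tuple(float(x) for x in q),
        std_errors=tuple(float(x) for x in w),
        pooled=qbar,
        within_var=wbar,
        between_var=between,
        total_se=total_se,
        m=m,
        level=level,
        ci_low=qbar - z * total_se,
        ci_high=qbar + z * total_se,
    )


def pool_log_scale(
    coefficients: Sequence[float],
    std_errors: Sequence[float],
    level: float = 0.95,
) -> PooledRatio:
    """Pool a log-link coefficient across imputations; report as a ratio.

    Pooling happens on the coefficient (log) scale; the point estimate
    and interval are exponentiated afterwards. The two-sided p-value
    uses the normal reference for pooled / total-SE.
    """
    pooled = pool(coefficients, std_errors, level=level)
    if pooled.total_se > 0:
        zstat = pooled.pooled / pooled.total_se
        p_value = 2 * stats.norm.sf(abs(zstat))
    else:
        p_value = 0.0 if pooled.pooled != 0 else 1.0
    return PooledRatio(
        ratio=math.exp(pooled.pooled),
        ci_low=math.exp(pooled.ci_low),
        ci_high=math.exp(pooled.ci_high),
        p_value=float(p_value),
        pooled=pooled,
    )


def format_pooled(pooled: PooledEstimate) -> str:
    lines = [
        "per-imputation estimates: "
        + ", ".join(f"{x:.6g}" for x in pooled.estimates),
        "per-imputation SEs:       "
        + ", ".join(f"{x:.6g}" for x in pooled.std_errors),
        f"pooled estimate: {pooled.pooled:.6g}",
        f"within variance: {pooled.within_var:.6g}",
        f"between variance: {pooled.between_var:.6g}",
        f"total SE: {pooled.total_se:.6g}",
        f"fraction of missing information: {pooled.fraction_missing_info:.4f}",
        f"{pooled.level:.0%} CI: ({pooled.ci_low:.6g}, {pooled.ci_high:.6g})",
    ]
    return "\n".join(lines) + "\n"
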
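"""Zero-inflated Poisson model for total minutes of intervention exposure.

The outcome is each participant's total viewing time rounded to whole
minutes. Participants who never accessed the program contribute exact
zeros, producing a point mass the Poisson cannot absorb, so the model
mixes a logistic "excess zero" component (intercept only) with a
log-linear Poisson count component:

    P(y=0)   = pi + (1-pi) exp(-mu_i)
    P(y=k>0) = (1-pi) exp(-mu_i) mu_i^k / k!
    logit pi = gamma0,   log mu_i = x_i' beta

With a common exposure period across participants, exp(beta_arm) is the
ratio of mean minutes between the two arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass
class ZipFit:
    param_names: list[str]  # "gamma0" first when zero-inflated
    params: np.ndarray
    std_errors: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    boundary: bool  # no zeros in the data: gamma0 driven to -inf
    zero_inflated: bool
    n: int

    @property
    def gamma0(self) -> float:
        return float(self.params[0]) if self.zero_inflated else -np.inf

    @property
    def pi(self) -> float:
        return float(special.expit(self.gamma0)) if np.isfinite(self.gamma0) else 0.0

    @property
    def beta(self) -> np.ndarray:
        return self.params[1:] if self.zero_inflated else self.params

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, SE) for a named parameter."""
        idx = self.param_names.index(name)
        return float(self.params[idx]), float(self.std_errors[idx])


@dataclass
class RatioResult:
    ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    note: str = ""


_GAMMA0_FLOOR = -30.0  # expit(-30) ~ 1e-13: numerically pi = 0


def total_time(
    durations: pd.DataFrame,
    participants: pd.DataFrame,
    rounding: str = "half-up",
) -> pd.DataFrame:
    """Per-participant total minutes and the integer count outcome.

    ``durations`` is a completed wide table indexed by participant_id
    (structural NaNs allowed); never-access participants total 0.
    Rounding to integer minutes is half-up by default ("floor" is the
    alternative).
    """
    totals = durations.sum(axis=1, skipna=True)
    frame = participants.astype({"participant_id": str}).set_index("participant_id")
    out = frame.join(totals.rename("total_min")).reset_index()
    # microminute pre-round: summation order must not flip half-up ties
    out["total_min"] = np.round(out["total_min"].fillna(0.0), 6)
    if rounding == "half-up":
        out["y"] = np.floor(out["total_min"] + 0.5).astype(int)
    elif rounding == "floor":
        out["y"] = np.floor(out["total_min"]).astype(int)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return out


def build_design(outcomes: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Poisson-part design: intercept, arm, stratum contrasts vs lowest."""
    n = len(outcomes)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append(outcomes["arm"].to_numpy(dtype=float))
    names.append("arm")
    strata = sorted(outcomes["stratum"].unique())
    for s in strata[1:]:
        cols.append((outcomes["stratum"] == s).to_numpy(dtype=float))
        names.append(f"stratum_{s}")
    return np.column_stack(cols), names


def zip_loglik(gamma0: float, beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Exact mixture log-likelihood (stable in gamma0)."""
    eta = X @ beta
    mu = np.exp(eta)
    zero = y == 0
    log_denom = np.logaddexp(0.0, gamma0)  # log(1 + e^gamma0)
    ll = 0.0
    if zero.any():
        ll += float(np.sum(np.logaddexp(gamma0, -mu[zero]) - log_denom))
    pos = ~zero
    if pos.any():
        ll += float(
            np.sum(
                -log_denom
                - mu[pos]
                + y[pos] * eta[pos]
                - special.gammaln(y[pos] + 1)
            )
        )
    return ll


def _nll_grad(theta: np.ndarray, y: np.ndarray, X: np.ndarray):
    gamma0 = theta[0]
    beta = theta[1:]
    eta = X @ beta
    mu = np.exp(eta)
    zero = y == 0
    pi_logit = special.expit(gamma0)
    n = y.size

    nll = -zip_loglik(gamma0, beta, y, X)

    # softmax weight of the structural-zero branch among zero outcomes
    w = special.expit(gamma0 + mu[zero])
    grad_gamma0 = float(np.sum(w) - n * pi_logit)
    grad_beta = np.zeros(beta.size)
    if zero.any():
        grad_beta += X[zero].T @ (-(1.0 - w) * mu[zero])
    pos = ~zero
    if pos.any():
        grad_beta += X[pos].T @ (y[pos] - mu[pos])
    return nll, -np.concatenate([[grad_gamma0], grad_beta])


def _poisson_nll_grad(beta: np.ndarray, y: np.ndarray, X: np.ndarray):
    eta = X @ beta
    mu = np.exp(eta)
    nll = float(np.sum(mu - y * eta + special.gammaln(y + 1)))
    grad = X.T @ (mu - y)
    return nll, grad


def _numeric_hessian(fun, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[:, j] = (gp - gm) / (2 * step)
    return (H + H.T) / 2


def _poisson_start(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Plain Poisson coefficients as a starting value (IRLS via statsmodels)."""
    import warnings

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Poisson())
            return np.asarray(model.fit().params, dtype=float)
    except Exception:
        beta = np.zeros(X.shape[1])
        beta[0] = math.log(max(y.mean(), 1e-6))
        return beta


def fit_zip(
    y: Sequence[int],
    X: np.ndarray,
    param_names: Optional[list[str]] = None,
    zero_inflation: bool = True,
) -> ZipFit:
    """Maximum-likelihood fit of the mixture (or plain Poisson).

    Multiple starting points (Poisson-based coefficients crossed with
    two zero-inflation starts) guard against local optima. Standard
    errors come from the inverted observed information at the optimum.
    Data with no zeros cannot identify gamma0 (the MLE is a boundary
    at -inf); that case is returned as a flagged boundary fit whose
    count part is the plain Poisson MLE.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be non-negative integers")
    names = list(param_names) if param_names else [
        f"x{j}" for j in range(X.shape[1])
    ]

    n_zero = int(np.sum(y == 0))
    boundary = zero_inflation and n_zero == 0

    if not zero_inflation or boundary:
        beta0 = _poisson_start(y, X)
        res = optimize.minimize(
            lambda b: _poisson_nll_grad(b, y, X),
            beta0,
            jac=True,
            method="L-BFGS-B",
        )
        H = _numeric_hessian(lambda b: _poisson_nll_grad(b, y, X), res.x)
        cov = _safe_inv(H)
        return ZipFit(
            param_names=names,
            params=res.x,
            std_errors=np.sqrt(np.maximum(np.diag(cov), 0)),
            cov=cov,
            llf=-res.fun,
            converged=bool(res.success),
            boundary=boundary,
            zero_inflated=False,
            n=y.size,
        )

    beta_start = _poisson_start(y, X)
    zero_frac = np.clip(n_zero / y.size, 1e-4, 1 - 1e-4)
    gamma_starts = [float(special.logit(zero_frac)), -5.0]
    # count-part start conditioned on being in the Poisson component
    beta_pos = beta_start.copy()
    if n_zero < y.size:
        beta_pos[0] = math.log(max(y[y > 0].mean(), 1e-6))

    best = None
    for g0 in gamma_starts:
        for b0 in (beta_start, beta_pos):
            theta0 = np.concatenate([[g0], b0])
            res = optimize.minimize(
                lambda t: _nll_grad(t, y, X),
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(_GAMMA0_FLOOR, -_GAMMA0_FLOOR)]
                + [(None, None)] * X.shape[1],
                options={"maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res

    theta = best.x
    H = _numeric_hessian(lambda t: _nll_grad(t, y, X), theta)
    cov = _safe_inv(H)
    at_floor = theta[0] <= _GAMMA0_FLOOR + 1e-6
    return ZipFit(
        param_names=["gamma0"] + names,
        params=theta,
        std_errors=np.sqrt(np.maximum(np.diag(cov), 0)),
        cov=cov,
        llf=-best.fun,
        converged=bool(best.success),
        boundary=at_floor,
        zero_inflated=True,
        n=y.size,
    )


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def fit_zip_outcomes(outcomes: pd.DataFrame, zero_inflation: bool = True) -> ZipFit:
    """Convenience wrapper: build the default design and fit."""
    X, names = build_design(outcomes)
    return fit_zip(outcomes["y"].to_numpy(), X, names, zero_inflation=zero_inflation)


def ratio_of_means(fit: ZipFit, term: str = "arm", level: float = 0.95) -> RatioResult:
    """Exponentiated count-part coefficient with its Wald interval."""
    if not fit.converged:
        return RatioResult(None, None, None, None, note="fit did not converge")
    est, se = fit.coef(term)
    if fit.boundary:
        return RatioResult(
            math.exp(est), None, None, None,
            note="zero-inflation parameter at the boundary; CI suppressed",
        )
    if se == 0 or not np.isfinite(se):
        return RatioResult(
            math.exp(est), None, None, None,
            note="standard error unavailable (boundary or singular information)",
        )
    z = stats.norm.ppf(0.5 + level / 2)
    p = 2 * stats.norm.sf(abs(est / se))
    return RatioResult(
        ratio=math.exp(est),
        ci_low=math.exp(est - z * se),
        ci_high=math.exp(est + z * se),
        p_value=float(p),
    )
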
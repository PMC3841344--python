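"""Zero-inflated Poisson fitting: oracles, recovery, and identities."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from timeoutmi import zipmodel
from timeoutmi.zipmodel import (
    RatioResult,
    build_design,
    fit_zip,
    fit_zip_outcomes,
    ratio_of_means,
    total_time,
    zip_loglik,
)


def _simulate_zip(n, pi, mu_by_arm, rng):
    """Direct draws from the mixture; returns an outcomes frame."""
    arm = rng.integers(0, 2, size=n)
    stratum = rng.integers(1, 4, size=n)
    mu = np.array([mu_by_arm[a] for a in arm], dtype=float)
    structural_zero = rng.random(n) < pi
    y = np.where(structural_zero, 0, rng.poisson(mu))
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "arm": arm,
            "stratum": stratum,
            "total_min": y.astype(float),
            "y": y,
        }
    )


class TestTotalTime:
    def test_simple_sum(self):
        durations = pd.DataFrame(
            {"t_1": [1.0], "t_2": [2.5], "t_3": [3.5]},
            index=pd.Index(["A"], name="participant_id"),
        )
        participants = pd.DataFrame(
            {"participant_id": ["A"], "arm": [1], "stratum": [1]}
        )
        out = total_time(durations, participants)
        assert out.loc[0, "total_min"] == 7.0
        assert out.loc[0, "y"] == 7

    def test_never_access_zero(self):
        durations = pd.DataFrame(
            {"t_1": [1.0, np.nan]},
            index=pd.Index(["A", "B"], name="participant_id"),
        )
        participants = pd.DataFrame(
            {"participant_id": ["A", "B"], "arm": [1, 0], "stratum": [1, 1]}
        )
        out = total_time(durations, participants).set_index("participant_id")
        assert out.loc["B", "total_min"] == 0.0
        assert out.loc["B", "y"] == 0

    @pytest.mark.parametrize("total,expected", [(7.4, 7), (7.5, 8), (0.5, 1)])
    def test_half_up_rounding(self, total, expected):
        durations = pd.DataFrame(
            {"t_1": [total]}, index=pd.Index(["A"], name="participant_id")
        )
        participants = pd.DataFrame(
            {"participant_id": ["A"], "arm": [0], "stratum": [1]}
        )
        assert total_time(durations, participants).loc[0, "y"] == expected

    def test_floor_rounding_option(self):
        durations = pd.DataFrame(
            {"t_1": [7.5]}, index=pd.Index(["A"], name="participant_id")
        )
        participants = pd.DataFrame(
            {"participant_id": ["A"], "arm": [0], "stratum": [1]}
        )
        out = total_time(durations, participants, rounding="floor")
        assert out.loc[0, "y"] == 7


class TestFitZip:
    def test_poisson_collapse_intercept_only(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, size=400) + 1  # strictly positive
        X = np.ones((y.size, 1))
        fit = fit_zip(y, X, ["intercept"], zero_inflation=False)
        assert math.exp(fit.params[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_grid_search_oracle_small_n(self):
        rng = np.random.default_rng(7)
        outcomes = _simulate_zip(30, 0.35, {0: 4.0, 1: 4.0}, rng)
        y = outcomes["y"].to_numpy()
        X = np.ones((30, 1))
        fit = fit_zip(y, X, ["intercept"])

        # two-stage dense grid over (gamma0, beta0), computed from the
        # likelihood formula written out independently
        def grid_max(g_lo, g_hi, b_lo, b_hi, steps):
            g = np.linspace(g_lo, g_hi, steps)
            b = np.linspace(b_lo, b_hi, steps)
            gg, bb = np.meshgrid(g, b, indexing="ij")
            mu = np.exp(bb)
            n0 = (y == 0).sum()
            npos = (y > 0).sum()
            s_pos = y[y > 0].sum()
            const = special.gammaln(y[y > 0] + 1).sum()
            ll = (
                n0 * (np.logaddexp(gg, -mu) - np.logaddexp(0, gg))
                + npos * (-np.logaddexp(0, gg) - mu)
                + s_pos * bb
                - const
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            return g[i], b[j], ll[i, j]

        g0, b0, _ = grid_max(-4, 4, -1, 3, 400)
        dg, db = 8 / 399, 4 / 399
        _, _, oracle = grid_max(g0 - dg, g0 + dg, b0 - db, b0 + db, 400)
        assert fit.llf >= oracle - 1e-6
        assert abs(fit.llf - oracle) < 1e-4

    def test_no_excess_zeros_matches_plain_poisson(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 600
        arm = rng.integers(0, 2, size=n)
        mu = np.exp(1.0 + 0.3 * arm)
        y = rng.poisson(mu)
        X = np.column_stack([np.ones(n), arm])
        fit = fit_zip(y, X, ["intercept", "arm"])
        assert fit.pi < 1e-3
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-3)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(21)
        true_pi = 0.37
        outcomes = _simulate_zip(5000, true_pi, {0: 8.0, 1: 8.0}, rng)
        fit = fit_zip_outcomes(outcomes)
        g_est, g_se = fit.coef("gamma0")
        assert abs(g_est - special.logit(true_pi)) < 3 * g_se
        a_est, a_se = fit.coef("arm")
        assert abs(a_est - 0.0) < 3 * a_se

    def test_mle_dominates_truth(self):
        rng = np.random.default_rng(5)
        outcomes = _simulate_zip(300, 0.3, {0: 5.0, 1: 4.0}, rng)
        fit = fit_zip_outcomes(outcomes)
        X, _ = build_design(outcomes)
        truth_ll = zip_loglik(
            float(special.logit(0.3)),
            np.array([math.log(5.0), math.log(4.0 / 5.0), 0.0, 0.0]),
            outcomes["y"].to_numpy().astype(float),
            X,
        )
        assert fit.llf >= truth_ll

    def test_no_zeros_is_boundary_fit(self):
        y = np.array([2, 3, 4, 5, 6])
        X = np.ones((5, 1))
        fit = fit_zip(y, X, ["intercept"])
        assert fit.boundary is True
        assert fit.pi == 0.0

    def test_rejects_non_integer_outcome(self):
        with pytest.raises(ValueError):
            fit_zip(np.array([1.5, 2.0]), np.ones((2, 1)))


class TestRatioOfMeans:
    def _fit_with(self, coef, se):
        return zipmodel.ZipFit(
            param_names=["gamma0", "intercept", "arm"],
            params=np.array([0.0, 1.0, coef]),
            std_errors=np.array([0.1, 0.1, se]),
            cov=np.eye(3),
            llf=-1.0,
            converged=True,
            boundary=False,
            zero_inflated=True,
            n=100,
        )

    def test_null_coefficient(self):
        result = ratio_of_means(self._fit_with(0.0, 0.05))
        assert result.ratio == pytest.approx(1.0)

    def test_exp_identity_with_hand_ci(self):
        from scipy import stats

        coef, se = math.log(0.87), 0.077
        result = ratio_of_means(self._fit_with(coef, se))
        z = stats.norm.ppf(0.975)
        assert result.ratio == pytest.approx(0.87)
        assert result.ci_low == pytest.approx(math.exp(coef - z * se))
        assert result.ci_high == pytest.approx(math.exp(coef + z * se))

    def test_boundary_suppresses_ci(self):
        fit = self._fit_with(0.1, 0.05)
        fit.boundary = True
        result = ratio_of_means(fit)
        assert result.ci_low is None
        assert "boundary" in result.note

    def test_recovery_of_simulated_ratio(self):
        rng = np.random.default_rng(11)
        outcomes = _simulate_zip(8000, 0.3, {0: 10.0, 1: 8.0}, rng)
        fit = fit_zip_outcomes(outcomes)
        result = ratio_of_means(fit)
        est, se = fit.coef("arm")
        assert abs(est - math.log(0.8)) < 3 * se
        assert result.ci_low < 0.8 < result.ci_high or abs(
            result.ratio - 0.8
        ) < 0.05


class TestModelIdentities:
    def test_arm_ratio_equals_count_part_mean_ratio(self):
        # with an intercept-only zero part, exp(beta_arm) is exactly the
        # ratio of model-implied count-part means at fixed stratum
        rng = np.random.default_rng(2)
        outcomes = _simulate_zip(2000, 0.4, {0: 6.0, 1: 5.0}, rng)
        fit = fit_zip_outcomes(outcomes)
        X, names = build_design(outcomes)
        beta = fit.beta
        x0 = np.array([1.0, 0.0] + [0.0] * (len(names) - 2))
        x1 = np.array([1.0, 1.0] + [0.0] * (len(names) - 2))
        implied = math.exp(x1 @ beta) / math.exp(x0 @ beta)
        assert implied == pytest.approx(math.exp(fit.coef("arm")[0]), rel=1e-12)
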
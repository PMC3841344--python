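"""Wide-format construction and the chained-equation imputation engine."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from timeoutmi import mice, weblog
from timeoutmi.mice import (
    IMPUTE,
    OBSERVED,
    STRUCTURAL,
    build_wide,
    diagnose_convergence,
    mice_impute,
)
from timeoutmi.weblog import ViewingRecord


def _rec(pid, pos, dur, timed_out=False, page="core-content", sec="quitting"):
    return ViewingRecord(pid, pos, None if timed_out else dur, timed_out, page, sec)


def _table(pids, **cols):
    data = {"participant_id": pids}
    defaults = {"arm": 0, "stratum": 1, "age": 45}
    for key, default in defaults.items():
        data[key] = cols.get(key, [default] * len(pids))
    return pd.DataFrame(data)


class TestBuildWide:
    def test_two_views_one_row(self):
        wide = build_wide(
            [_rec("A", 1, 1.0), _rec("A", 2, 2.0)], _table(["A"])
        )
        assert wide.durations.loc["A", "t_1"] == 1.0
        assert wide.durations.loc["A", "t_2"] == 2.0
        assert (wide.mask.loc["A"] == OBSERVED).all()

    def test_timed_out_view_masked_for_imputation(self):
        wide = build_wide(
            [_rec("A", 1, 1.0), _rec("A", 2, None, timed_out=True)],
            _table(["A"]),
        )
        assert np.isnan(wide.durations.loc["A", "t_2"])
        assert wide.mask.loc["A", "t_2"] == IMPUTE

    def test_no_views_all_structural(self):
        wide = build_wide([_rec("A", 1, 1.0)], _table(["A", "B"]))
        assert (wide.mask.loc["B"] == STRUCTURAL).all()

    def test_unknown_participant_named_in_error(self):
        with pytest.raises(KeyError, match="ZZZ"):
            build_wide([_rec("ZZZ", 1, 1.0)], _table(["A"]))

    def test_width_is_max_position(self, default_records, default_cohort):
        wide = build_wide(default_records, default_cohort.participants)
        assert wide.n_positions == max(r.position for r in default_records)


@pytest.fixture(scope="module")
def cohort_wide():
    from timeoutmi import simulate

    config = simulate.SimulationConfig(n_participants=400, seed=77)
    cohort = simulate.generate_cohort(config)
    events = weblog.events_from_frame(cohort.events)
    records = weblog.compute_durations(events, config.timeout_min)
    return build_wide(records, cohort.participants)


class TestMiceImpute:
    def test_nothing_to_impute_returns_identical_copies(self):
        wide = build_wide(
            [_rec("A", 1, 1.0), _rec("A", 2, 2.0)], _table(["A", "B"])
        )
        result = mice_impute(wide, m=3, iterations=2, seed=0)
        assert len(result.imputed) == 3
        for ds in result.imputed:
            assert ds.durations.equals(wide.durations)

    def test_five_completed_datasets(self, cohort_wide):
        result = mice_impute(cohort_wide, m=5, iterations=3, seed=1)
        assert len(result.imputed) == 5
        assert [ds.m for ds in result.imputed] == [1, 2, 3, 4, 5]

    def test_observed_cells_preserved_bitwise(self, cohort_wide):
        result = mice_impute(cohort_wide, m=3, iterations=3, seed=2)
        obs = cohort_wide.mask.to_numpy() == OBSERVED
        original = cohort_wide.durations.to_numpy()
        for ds in result.imputed:
            completed = ds.durations.to_numpy()
            assert np.array_equal(original[obs], completed[obs])

    def test_structural_cells_stay_absent(self, cohort_wide):
        result = mice_impute(cohort_wide, m=2, iterations=2, seed=3)
        structural = cohort_wide.mask.to_numpy() == STRUCTURAL
        for ds in result.imputed:
            assert np.isnan(ds.durations.to_numpy()[structural]).all()

    def test_imputed_durations_strictly_positive(self, cohort_wide):
        result = mice_impute(cohort_wide, m=2, iterations=2, seed=4)
        imput = cohort_wide.mask.to_numpy() == IMPUTE
        for ds in result.imputed:
            assert (ds.durations.to_numpy()[imput] > 0).all()

    def test_between_imputation_variance_positive(self, cohort_wide):
        result = mice_impute(cohort_wide, m=4, iterations=2, seed=5)
        imput = cohort_wide.mask.to_numpy() == IMPUTE
        stacks = np.stack([ds.durations.to_numpy()[imput] for ds in result.imputed])
        assert (stacks.var(axis=0) > 0).all()

    def test_seeded_determinism(self, cohort_wide):
        a = mice_impute(cohort_wide, m=2, iterations=2, seed=9)
        b = mice_impute(cohort_wide, m=2, iterations=2, seed=9)
        for da, db in zip(a.imputed, b.imputed):
            assert da.durations.equals(db.durations)
        assert a.traces.equals(b.traces)

    def test_truncation_switch(self, cohort_wide):
        result = mice_impute(
            cohort_wide, m=2, iterations=2, seed=6, truncate_at=30.0
        )
        imput = cohort_wide.mask.to_numpy() == IMPUTE
        for ds in result.imputed:
            assert (ds.durations.to_numpy()[imput] <= 30.0).all()

    def test_unimputable_column_is_named(self):
        # every observation of t_1 timed out and there is no sparse
        # partner position to pool with
        records = [_rec(f"P{i}", 1, None, timed_out=True) for i in range(30)]
        wide = build_wide(records, _table([f"P{i}" for i in range(30)]))
        with pytest.raises(ValueError, match="t_1"):
            mice_impute(wide, m=2, iterations=1, seed=0)

    def test_closed_form_regression_oracle(self):
        # single missing cell, one continuous predictor: the mean of many
        # imputed draws must agree with the closed-form least-squares
        # prediction at that predictor value
        rng = np.random.default_rng(123)
        n = 5000
        x = rng.normal(0, 1, size=n)
        log_t = 0.3 + 0.5 * x + 0.4 * rng.standard_normal(n)
        durations = np.exp(log_t)
        records = [
            _rec(f"P{i}", 1, float(durations[i]), timed_out=(i == 0))
            for i in range(n)
        ]
        participants = pd.DataFrame(
            {"participant_id": [f"P{i}" for i in range(n)], "x": x}
        )
        wide = build_wide(records, participants)
        result = mice_impute(wide, m=50, iterations=1, seed=7)
        draws = np.log(
            [ds.durations.loc["P0", "t_1"] for ds in result.imputed]
        )
        coeffs = np.polyfit(x[1:], log_t[1:], 1)  # independent oracle
        prediction = coeffs[1] + coeffs[0] * x[0]
        se_mean = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - prediction) < 3 * se_mean


class TestConvergenceDiagnostics:
    def test_empty_when_nothing_imputed(self):
        wide = build_wide([_rec("A", 1, 1.0)], _table(["A"]))
        result = mice_impute(wide, m=2, iterations=3, seed=0)
        assert diagnose_convergence(result.traces).empty

    def test_trace_shape(self, cohort_wide):
        result = mice_impute(cohort_wide, m=2, iterations=4, seed=0)
        table = diagnose_convergence(result.traces)
        assert set(table.columns) == {"column", "iteration", "mean_min", "sd_min"}
        assert table["iteration"].max() == 4

    def test_two_seed_stationarity(self, cohort_wide):
        # final-iteration imputed means from two independent seeds agree
        # within Monte-Carlo error (pooled over columns)
        a = mice_impute(cohort_wide, m=3, iterations=6, seed=100)
        b = mice_impute(cohort_wide, m=3, iterations=6, seed=200)

        def final_means(result):
            tr = result.traces
            last = tr[tr["iteration"] == tr["iteration"].max()]
            return last.groupby("column")["mean_min"].mean(), last.groupby(
                "column"
            )["mean_min"].std(ddof=1)

        mean_a, sd_a = final_means(a)
        mean_b, sd_b = final_means(b)
        for col in mean_a.index:
            pooled_se = np.sqrt(
                (sd_a[col] ** 2 + sd_b[col] ** 2) / 3 + 1e-12
            )
            assert abs(mean_a[col] - mean_b[col]) < 4 * pooled_se + 0.75


class TestManifest:
    def test_write_imputed_roundtrip(self, cohort_wide, tmp_path):
        result = mice_impute(cohort_wide, m=2, iterations=2, seed=0)
        paths = mice.write_imputed(result, tmp_path)
        first = pd.read_csv(paths["imputed_1"], index_col="participant_id")
        assert (first["m"] == 1).all()
        import json

        manifest = json.loads(open(paths["manifest"]).read())
        assert manifest["m"] == 2
        assert manifest["models"]

    def test_model_specs_exclude_target(self, cohort_wide):
        result = mice_impute(cohort_wide, m=2, iterations=2, seed=0)
        for spec in result.model_specs:
            assert spec.target not in spec.predictors
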
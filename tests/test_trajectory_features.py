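"""Trajectory feature engineering: the 8-measure summary, the column-count
law, and leakage-safe median imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icurisk.trajectory_features import (TRAJECTORY_MEASURES, apply_impute,
                                         build_feature_matrix, build_raw_summaries,
                                         fit_impute, ls_slope, summarize_variable)

SLOPE_3PT = 0.019933554817275666  # normal-equations oracle for (1,7),(5,9),(20,8)


class TestLsSlope:
    @pytest.mark.parametrize("pts,expected", [
        ([(0, 10), (12, 13), (24, 16)], 0.25),       # collinear
        ([(0, 5), (24, 5)], 0.0),                    # flat
        ([(1, 7), (5, 9), (20, 8)], SLOPE_3PT),
    ])
    def test_known_values(self, pts, expected):
        assert ls_slope(pts) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_missing(self):
        assert np.isnan(ls_slope([]))
        assert np.isnan(ls_slope([(2.0, 5.0)]))
        assert np.isnan(ls_slope([(3.0, 1.0), (3.0, 2.0)]))  # all t equal

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 24), st.floats(-100, 100)),
                    min_size=2, max_size=12))
    def test_matches_polyfit(self, pts):
        t = np.array([p[0] for p in pts])
        if np.ptp(t) < 1e-9:
            return
        ours = ls_slope(pts)
        ref = np.polyfit(t, [p[1] for p in pts], 1)[0]
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-8)


class TestSummarizeVariable:
    def test_hand_computed_summary(self):
        s = summarize_variable([1, 5, 20], [7, 9, 8])
        assert s["min"] == 7 and s["max"] == 9 and s["mean"] == 8
        assert s["sd"] == pytest.approx(1.0)
        assert s["first"] == 7 and s["last"] == 8 and s["delta"] == 1
        assert s["slope"] == pytest.approx(SLOPE_3PT)

    def test_single_observation_degenerate(self):
        s = summarize_variable([2], [5])
        for m in ("min", "max", "mean", "first", "last"):
            assert s[m] == 5
        for m in ("sd", "delta", "slope"):
            assert np.isnan(s[m])

    def test_no_observations_all_missing(self):
        s = summarize_variable([], [])
        assert all(np.isnan(s[m]) for m in TRAJECTORY_MEASURES)

    def test_first_last_tie_by_input_order(self):
        s = summarize_variable([3.0, 3.0], [1.0, 2.0])
        assert s["first"] == 1.0 and s["last"] == 2.0


def _toy_tables():
    stays = pd.DataFrame({
        "patient_id": ["p1", "p2"],
        "died_in_hospital": [False, True],
    })
    obs = pd.DataFrame({
        "patient_id": ["p1", "p1", "p1", "p2"],
        "variable": ["gcs", "gcs", "gcs", "gcs"],
        "t": [1.0, 5.0, 20.0, 2.0],
        "value": [7.0, 9.0, 8.0, 5.0],
    })
    return stays, obs


class TestBuildFeatureMatrix:
    def test_column_count_law(self):
        """2V baseline / 8V trajectory columns for any V."""
        rng = np.random.default_rng(0)
        for V in (1, 3, 24):
            variables = [f"v{i}" for i in range(V)]
            obs = pd.DataFrame({
                "patient_id": ["p"] * (2 * V),
                "variable": np.repeat(variables, 2),
                "t": np.tile([1.0, 2.0], V),
                "value": rng.normal(size=2 * V),
            })
            stays = pd.DataFrame({"patient_id": ["p"], "died_in_hospital": [True]})
            base = build_feature_matrix(stays, obs, variables, mode="baseline")
            traj = build_feature_matrix(stays, obs, variables, mode="trajectory")
            assert base.n_predictors == 2 * V
            assert traj.n_predictors == 8 * V

    def test_composition_matches_summarize(self):
        stays, obs = _toy_tables()
        fm = build_feature_matrix(stays, obs, ["gcs"], mode="trajectory")
        assert fm.n_predictors == 8
        expected = summarize_variable([1, 5, 20], [7, 9, 8])
        row = dict(zip(fm.columns, fm.X[0]))
        for m in TRAJECTORY_MEASURES:
            assert row[f"gcs__{m}"] == pytest.approx(expected[m], abs=1e-12)

    def test_baseline_values_subset_of_trajectory(self):
        stays, obs = _toy_tables()
        base = build_feature_matrix(stays, obs, ["gcs"], mode="baseline")
        traj = build_feature_matrix(stays, obs, ["gcs"], mode="trajectory")
        for col in base.columns:
            j_b, j_t = base.columns.index(col), traj.columns.index(col)
            np.testing.assert_array_equal(base.X[:, j_b], traj.X[:, j_t])

    def test_unknown_variable_is_config_error(self):
        stays, obs = _toy_tables()
        with pytest.raises(ValueError, match="unknown variable"):
            build_feature_matrix(stays, obs, ["gcs", "nope"], mode="baseline")

    def test_column_order_variable_major(self):
        stays, obs = _toy_tables()
        obs2 = pd.concat([obs, obs.assign(variable="hr")])
        fm = build_feature_matrix(stays, obs2, ["gcs", "hr"], mode="baseline")
        assert fm.columns == ["gcs__min", "gcs__max", "hr__min", "hr__max"]

    def test_vectorized_summaries_match_rowwise(self, small_cohort):
        cfg, stays, obs, notes = small_cohort
        variables = [v.name for v in cfg.variable_specs]
        raw = build_raw_summaries(obs, variables)
        rng = np.random.default_rng(0)
        pids = rng.choice(obs["patient_id"].unique(), 10, replace=False)
        for pid in pids:
            for var in variables:
                sub = obs[(obs["patient_id"] == pid) & (obs["variable"] == var)]
                expected = summarize_variable(sub["t"].tolist(), sub["value"].tolist())
                for m in TRAJECTORY_MEASURES:
                    got = raw.loc[pid, f"{var}__{m}"]
                    if np.isnan(expected[m]):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(expected[m], rel=1e-9)


class TestImputation:
    def _matrix(self, X):
        from icurisk.trajectory_features import FeatureMatrix
        return FeatureMatrix(patient_ids=[f"p{i}" for i in range(len(X))],
                             columns=[f"c{j}" for j in range(X.shape[1])],
                             X=X, y=np.zeros(len(X), dtype=int))

    def test_median_fills_missing(self):
        X = np.array([[1.0], [2.0], [np.nan], [4.0]])
        out = fit_impute(self._matrix(X))
        assert out.X[2, 0] == 2.0  # median of {1,2,4}
        assert out.imputation_medians[0] == 2.0

    def test_no_missing_identity(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        out = fit_impute(self._matrix(X))
        np.testing.assert_array_equal(out.X, X)
        np.testing.assert_array_equal(out.imputation_medians, np.median(X, axis=0))

    def test_all_missing_predictor_instructs_drop(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="drop"):
            fit_impute(self._matrix(X))

    def test_random_missingness_matches_brute_force(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        X[rng.random(X.shape) < 0.3] = np.nan
        X[0, :] = 1.0  # ensure no all-missing column
        out = fit_impute(self._matrix(X))
        for j in range(6):
            col = X[:, j]
            med = float(np.median(sorted(col[~np.isnan(col)])))
            assert out.imputation_medians[j] == pytest.approx(med)
            np.testing.assert_allclose(out.X[np.isnan(col), j], med)

    def test_leakage_law_test_rows_cannot_move_medians(self):
        rng = np.random.default_rng(5)
        X_train = rng.normal(size=(30, 4))
        X_train[rng.random(X_train.shape) < 0.2] = np.nan
        X_train[0, :] = 0.0
        fitted = fit_impute(self._matrix(X_train))
        medians = fitted.imputation_medians.copy()
        X_test = rng.normal(size=(10, 4)) * 100  # wildly different test rows
        X_test[0, 0] = np.nan
        applied = apply_impute(self._matrix(X_test), medians)
        np.testing.assert_array_equal(applied.imputation_medians, medians)
        assert applied.X[0, 0] == medians[0]
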
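"""Harness bookkeeping, leakage laws, cross-site structure, the
alive-at-24-h sensitivity analysis, and construct validity."""

import numpy as np

from icurisk.harness import (HarnessConfig, construct_validity, cross_site,
                             fit_pipeline, nested_cv, predict_pipeline, prepare,
                             sensitivity_alive_24h, split_by_site)
from icurisk.ridge_logistic import stratified_folds
from icurisk.trajectory_features import FeatureMatrix
from icurisk.synthetic_ehr import generate_cohort

from conftest import small_generator_config


def _tiny_config(**kw):
    base = dict(outer_folds=4, repetitions=1, inner_folds=2, bootstrap=200,
                vocab_k=30, lambda_grid=(1.0,), seed=0)
    base.update(kw)
    return HarnessConfig(**base)


class TestNestedCVBookkeeping:
    def test_r_times_k_fold_aucs(self, small_prep):
        cfg = _tiny_config(repetitions=2, outer_folds=5)
        res = nested_cv(small_prep, cfg)
        for mode in cfg.model_modes:
            assert len(res[mode].fold_aucs) == 10
            assert all(0.0 <= a <= 1.0 for a in res[mode].fold_aucs)

    def test_deterministic_for_fixed_seed(self, small_prep):
        cfg = _tiny_config(repetitions=1, outer_folds=4, model_modes=("baseline",))
        a = nested_cv(small_prep, cfg)
        b = nested_cv(small_prep, cfg)
        assert a["baseline"].fold_aucs == b["baseline"].fold_aucs
        np.testing.assert_array_equal(a["baseline"].oof_risks, b["baseline"].oof_risks)

    def test_out_of_fold_risks_cover_everyone(self, small_prep):
        cfg = _tiny_config(model_modes=("trajectory",))
        res = nested_cv(small_prep, cfg)
        assert not np.isnan(res["trajectory"].oof_risks).any()

    def test_ci_brackets_point_estimate(self, small_prep):
        cfg = _tiny_config(repetitions=2, outer_folds=5, model_modes=("baseline",))
        res = nested_cv(small_prep, cfg)
        lo, hi = res["baseline"].discrimination.auc_ci
        assert lo <= res["baseline"].discrimination.auc <= hi


class TestLeakage:
    def test_mutating_test_fold_leaves_artifacts_bit_identical(self, small_prep):
        """Values and note text of held-out patients cannot move any
        fit-time artifact: medians, vocabulary, idf, lambda,
        standardization, coefficients."""
        prep = small_prep
        y = prep.y
        folds = stratified_folds(y, 4, np.random.default_rng(0))
        test_idx = folds[0]
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        pids = np.array(prep.patient_ids)
        train_ids, test_ids = pids[train_idx], pids[test_idx]
        cfg = _tiny_config(lambda_grid=(0.1, 10.0))

        pipe_before = fit_pipeline(prep, train_ids, "trajectory+nlp", cfg, seed=5)

        # corrupt every held-out patient's data
        mutated = prep.subset(np.ones(len(y), dtype=bool))
        mutated.raw = prep.raw.copy()
        mutated.raw.loc[list(test_ids), :] = 9999.0
        mutated.note_sets = dict(prep.note_sets)
        from collections import Counter
        for pid in test_ids:
            mutated.note_sets[pid] = Counter({"corrupted": 500, "garbage": 300})

        pipe_after = fit_pipeline(mutated, train_ids, "trajectory+nlp", cfg, seed=5)

        np.testing.assert_array_equal(pipe_before.medians, pipe_after.medians)
        assert pipe_before.vocab.terms == pipe_after.vocab.terms
        assert pipe_before.vocab.idf == pipe_after.vocab.idf
        assert pipe_before.lam == pipe_after.lam
        np.testing.assert_array_equal(pipe_before.model.means_, pipe_after.model.means_)
        np.testing.assert_array_equal(pipe_before.model.sds_, pipe_after.model.sds_)
        np.testing.assert_array_equal(pipe_before.model.coef_, pipe_after.model.coef_)

    def test_test_fold_vocabulary_terms_never_enter(self, small_prep):
        """A term appearing only in held-out notes is absent from the
        fitted vocabulary."""
        prep = small_prep
        pids = np.array(prep.patient_ids)
        train_ids = pids[: len(pids) // 2]
        held_out = pids[len(pids) // 2]
        from collections import Counter
        prep_mut = prep.subset(np.ones(len(pids), dtype=bool))
        prep_mut.note_sets = dict(prep.note_sets)
        prep_mut.note_sets[held_out] = Counter({"zzzunique": 1000})
        pipe = fit_pipeline(prep_mut, train_ids, "trajectory+nlp", _tiny_config(), seed=1)
        assert "zzzunique" not in pipe.vocab.terms


class TestCrossSite:
    def test_matrix_structure(self, multisite_prep):
        cfg = _tiny_config(model_modes=("baseline", "trajectory"))
        mat = cross_site(split_by_site(multisite_prep), cfg)
        for mode in cfg.model_modes:
            assert len(mat.aucs[mode]) == 2  # 2 ordered pairs for 2 sites
            for (a, b), v in mat.aucs[mode].items():
                assert a != b and 0.0 <= v <= 1.0
        table = mat.table("baseline")
        assert np.isnan(np.diag(table.to_numpy().astype(float))).all()

    def test_three_sites_give_six_cells(self):
        cfg3 = small_generator_config(
            n=400, seed=31, sites={"a": 0.34, "b": 0.33, "c": 0.33})
        stays, obs, notes = generate_cohort(cfg3)
        prep = prepare(stays, obs, notes, [v.name for v in cfg3.variable_specs])
        mat = cross_site(split_by_site(prep), _tiny_config(model_modes=("baseline",)))
        assert len(mat.aucs["baseline"]) == 6

    def test_identical_sites_transfer_like_within_site(self, multisite_prep):
        """Two sites drawn from the same generative process: transfer AUC
        falls within the spread of within-site CV AUC."""
        cfg = _tiny_config(model_modes=("trajectory",), repetitions=2, outer_folds=4,
                           lambda_grid=(1.0,))
        preps = split_by_site(multisite_prep)
        mat = cross_site(preps, cfg)
        transfer = np.mean(list(mat.aucs["trajectory"].values()))
        within = nested_cv(list(preps.values())[0], cfg)["trajectory"].fold_aucs
        spread = 4 * np.std(within, ddof=1)
        assert abs(transfer - np.mean(within)) < max(spread, 0.08)

    def test_out_of_vocabulary_patients_score_zero_text_signal(self, multisite_prep):
        """Disjoint vocabularies: a test patient with no in-vocabulary term
        gets identical risk whatever their notes say."""
        preps = split_by_site(multisite_prep)
        (sa, prep_a), (sb, prep_b) = list(preps.items())
        pipe = fit_pipeline(prep_a, prep_a.patient_ids, "trajectory+nlp",
                            _tiny_config(), seed=2)
        from collections import Counter
        target = prep_b.patient_ids[0]
        prep_oov = prep_b.subset(np.ones(len(prep_b.patient_ids), dtype=bool))
        prep_oov.note_sets = dict(prep_b.note_sets)
        prep_oov.note_sets[target] = Counter({"qqqq": 7})   # fully out-of-vocabulary
        r1 = predict_pipeline(pipe, prep_oov, [target])
        prep_oov.note_sets[target] = Counter({"xxxx": 999})  # different OOV content
        r2 = predict_pipeline(pipe, prep_oov, [target])
        assert r1[0] == r2[0]


class TestSensitivityAlive24h:
    def test_no_early_deaths_identical_to_full_cv(self, small_prep):
        mask = (small_prep.stays["death_time_hours"].isna()
                | (small_prep.stays["death_time_hours"] >= 24)).to_numpy()
        prep_late = small_prep.subset(mask)
        cfg = _tiny_config(model_modes=("baseline",))
        full = nested_cv(prep_late, cfg)
        sens = sensitivity_alive_24h(prep_late, cfg)
        assert full["baseline"].fold_aucs == sens["baseline"].fold_aucs

    def test_early_death_fraction_and_prevalence_drop(self):
        cfg = small_generator_config(n=6000, seed=41, tokens_per_note_mean=5.0,
                                     notes_per_patient_mean=1.0)
        stays, obs, notes = generate_cohort(cfg)
        prep = prepare(stays, obs, notes, [v.name for v in cfg.variable_specs])
        death = prep.stays["death_time_hours"]
        alive = death.isna() | (death >= 24)
        deaths_total = int(prep.y.sum())
        deaths_restricted = int(prep.subset(alive.to_numpy()).y.sum())
        frac_kept = deaths_restricted / deaths_total
        se = np.sqrt(0.147 * 0.853 / deaths_total)
        assert abs(frac_kept - 0.853) < 3 * se
        restricted_prev = prep.subset(alive.to_numpy()).y.mean()
        assert restricted_prev < prep.y.mean()


class TestConstructValidity:
    def test_constant_feature_null(self):
        fm = FeatureMatrix(patient_ids=["a", "b", "c", "d"], columns=["c0"],
                           X=np.ones((4, 1)), y=np.array([0, 0, 1, 1]))
        out = construct_validity(fm)
        row = out.iloc[0]
        assert row["mean_survivor"] == row["mean_nonsurvivor"] == 1.0
        assert row["wilcoxon_p"] == 1.0

    def test_outcome_independent_feature_small_effect(self):
        rng = np.random.default_rng(10)
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 4000
            y = (rng.random(n) < 0.1).astype(int)
            x = rng.normal(size=(n, 1))
            fm = FeatureMatrix(patient_ids=[str(i) for i in range(n)],
                               columns=["noise"], X=x, y=y)
            out = construct_validity(fm).iloc[0]
            smd = abs(out["mean_survivor"] - out["mean_nonsurvivor"]) / x.std()
            hits += smd < 0.1
        assert hits / reps >= 0.95

    def test_signal_feature_detected(self):
        from icurisk.trajectory_features import build_feature_matrix
        cfg = small_generator_config(n=1500, seed=17, tokens_per_note_mean=5.0,
                                     notes_per_patient_mean=1.0)
        stays, obs, notes = generate_cohort(cfg)
        prep = prepare(stays, obs, notes, [v.name for v in cfg.variable_specs])
        fm = build_feature_matrix(prep.stays, None, prep.variables,
                                  mode="trajectory", raw=prep.raw)
        out = construct_validity(fm).set_index("predictor")
        row = out.loc["gcs_total__slope"]
        assert row["mean_survivor"] > row["mean_nonsurvivor"]
        assert row["wilcoxon_p"] < 0.001
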
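"""Tabular/hybrid experiments: outcome dichotomization, the ASTRAL
comparator, cohort cleaning, coefficient profiles, paired t-tests, VIF
and the cross-validated logistic experiments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strokeprog.hybrid import (EXPERIMENTS, ExperimentDef, astral_score,
                               astral_scores, bayes_opt_lr, clean_cohort,
                               comparison_report, dichotomize_mrs,
                               normalized_coefficients, paired_t_test,
                               run_lr_experiment, vif)
from strokeprog.synthetic import CohortSpec, gen_cohort


class TestDichotomize:
    def test_exhaustive_table(self):
        for mrs, want in [(0, 0), (1, 0), (2, 0), (3, 1), (4, 1), (5, 1), (6, 1)]:
            assert dichotomize_mrs(mrs) == want

    def test_array_form(self):
        out = dichotomize_mrs(np.array([0, 2, 3, 6]))
        assert np.array_equal(out, [0, 0, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_mrs(7)
        with pytest.raises(ValueError):
            dichotomize_mrs(-1)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_mrs(np.array([1.5]))


class TestAstral:
    def test_floor_case_scores_zero(self):
        rec = {"age": 4, "nihss": 0, "delay": 1.0, "visual_defect": 0,
               "loc": 0, "glucose": 100.0}
        assert astral_score(rec) == 0

    def test_hand_case_median_patient(self):
        # 71 y -> 14, NIHSS 7 -> 7, 2 h -> 0, visual defect -> 2,
        # no LOC -> 0, glucose 120 in range -> 0; total 23
        rec = {"age": 71, "nihss": 7, "delay": 2.0, "visual_defect": 1,
               "loc": 0, "glucose": 120.0}
        assert astral_score(rec) == 23

    def test_boundary_conditions(self):
        base = {"age": 0, "nihss": 0, "delay": 3.0, "visual_defect": 0,
                "loc": 0, "glucose": 131.0}
        assert astral_score(base) == 0  # both thresholds strict
        assert astral_score({**base, "delay": 3.01}) == 2
        assert astral_score({**base, "glucose": 131.5}) == 1
        assert astral_score({**base, "glucose": 65.9}) == 1
        assert astral_score({**base, "age": 74}) == 14  # floor(74/5)=14

    def test_monotone_in_age_and_nihss(self):
        rec = {"age": 60, "nihss": 5, "delay": 1.0, "visual_defect": 0,
               "loc": 0, "glucose": 100.0}
        s0 = astral_score(rec)
        assert astral_score({**rec, "age": 80}) > s0
        assert astral_score({**rec, "nihss": 15}) > s0

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError):
            astral_score({"age": 70, "nihss": 5})

    def test_vectorized_matches_scalar(self, cohort_table):
        cohort, _ = cohort_table
        sub = clean_cohort(cohort).head(20)
        vec = astral_scores(sub)
        assert np.array_equal(vec, [astral_score(r) for _, r in sub.iterrows()])


class TestCleanCohort:
    def _frame(self):
        n = 6
        return pd.DataFrame({
            "age": [70.0, 70.0, np.nan, 70.0, 70.0, 150.0],
            "nihss": [5] * 6, "delay": [2.0] * 6, "visual_defect": [0] * 6,
            "loc": [0] * 6, "glucose": [100.0, 900.0, 100.0, 100.0, 100.0, 100.0],
            "aspects": [9] * 6, "occlusion": [1.0] * 6,
            "mrs90": [2, 2, 2, np.nan, 2, 2],
        })

    def test_drops_missing_and_out_of_bounds(self):
        out = clean_cohort(self._frame())
        assert len(out) == 2  # rows 0 and 4 survive

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            clean_cohort(self._frame().drop(columns=["glucose"]))

    def test_all_dropped_rejected(self):
        frame = self._frame()
        frame["age"] = np.nan
        with pytest.raises(ValueError):
            clean_cohort(frame)


class TestCoefficients:
    def test_hand_case_normalization(self):
        out = normalized_coefficients([np.array([3.0, -1.0])], ["a", "b"])
        assert out.loc[out.variable == "a", "mean"].item() == pytest.approx(0.75)
        assert out.loc[out.variable == "b", "mean"].item() == pytest.approx(0.25)

    def test_rows_sum_to_one_and_scale_invariant(self, rng):
        folds = [rng.normal(size=4) for _ in range(5)]
        names = list("abcd")
        a = normalized_coefficients(folds, names)
        b = normalized_coefficients([10.0 * f for f in folds], names)
        assert a["mean"].sum() == pytest.approx(1.0)
        pd.testing.assert_frame_equal(a, b)

    def test_sorted_descending(self, rng):
        out = normalized_coefficients([rng.normal(size=5) for _ in range(3)],
                                      list("abcde"))
        assert (np.diff(out["mean"].to_numpy()) <= 1e-12).all()

    def test_all_zero_fold_warns_and_excluded(self):
        with pytest.warns(UserWarning):
            out = normalized_coefficients(
                [np.zeros(2), np.array([1.0, 1.0])], ["a", "b"])
        assert np.allclose(out["mean"], 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalized_coefficients([np.ones(3)], ["a", "b"])


class TestPairedT:
    def test_matches_closed_form_t_cdf(self, rng):
        a = rng.normal(0.8, 0.05, 10)
        b = rng.normal(0.75, 0.05, 10)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        oracle = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        p, sig, direction = paired_t_test(a, b)
        assert p == pytest.approx(oracle, rel=1e-10)
        assert sig == (p < 0.05)
        assert direction == ("a_higher" if d.mean() > 0 else "b_higher")

    def test_hand_t_statistic(self):
        # d = [1, 2, 3]: mean 2, sd 1, t = 2*sqrt(3), df 2
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        p, _, direction = paired_t_test(a, b)
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2))
        assert direction == "a_higher"

    def test_identical_vectors_p_one(self):
        p, sig, direction = paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (p, sig, direction) == (1.0, False, "equal")

    def test_constant_nonzero_difference(self):
        with pytest.warns(UserWarning):
            p, sig, direction = paired_t_test([0.6, 0.7], [0.5, 0.6])
        assert (p, sig, direction) == (0.0, True, "a_higher")

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([0.5], [0.4])
        with pytest.raises(ValueError):
            paired_t_test([0.5, 0.6], [0.4, 0.5, 0.6])


class TestVif:
    def test_orthogonal_design_near_one(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(60, 3)))
        out = vif(q)
        assert np.allclose(out["vif"], 1.0, atol=1e-6)
        assert not out["flagged"].any()

    def test_duplicate_column_inf_flagged(self, rng):
        col = rng.normal(size=50)
        out = vif(np.column_stack([col, col, rng.normal(size=50)]))
        assert np.isinf(out["vif"][0]) and np.isinf(out["vif"][1])
        assert out["flagged"][0] and out["flagged"][1]
        assert np.isfinite(out["vif"][2])

    def test_matches_regression_oracle(self, rng):
        x = rng.normal(size=(80, 4))
        x[:, 3] = 0.7 * x[:, 0] + 0.3 * x[:, 1] + 0.2 * rng.normal(size=80)
        x = (x - x.mean(axis=0)) / x.std(axis=0)  # standardized, per contract
        out = vif(x)
        for j in range(4):
            design = np.delete(x, j, axis=1)
            beta, *_ = np.linalg.lstsq(design, x[:, j], rcond=None)
            resid = x[:, j] - design @ beta
            r2 = 1 - (resid ** 2).sum() / (x[:, j] ** 2).sum()
            assert out["vif"][j] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_shape_and_constant_column_rejected(self, rng):
        with pytest.raises(ValueError):
            vif(rng.normal(size=(3, 5)))
        bad = rng.normal(size=(30, 2))
        bad[:, 1] = 2.0
        with pytest.raises(ValueError):
            vif(bad)


class TestBayesOpt:
    def _xy(self, rng, n=120):
        x = rng.normal(size=(n, 3))
        y = (x[:, 0] + 0.5 * x[:, 1] + rng.normal(scale=0.5, size=n) > 0)
        return x, y.astype(int)

    def test_budget_zero_default_with_warning(self, rng):
        x, y = self._xy(rng)
        with pytest.warns(UserWarning):
            params, trials = bayes_opt_lr(x, y, budget=0)
        assert params == {"C": 1.0, "penalty": "l2"} and trials == []

    def test_negative_budget_rejected(self, rng):
        x, y = self._xy(rng)
        with pytest.raises(ValueError):
            bayes_opt_lr(x, y, budget=-1)

    def test_budget_respected_and_best_is_argmax(self, rng):
        x, y = self._xy(rng)
        params, trials = bayes_opt_lr(x, y, budget=6, seed=0)
        assert len(trials) == 6
        best = max(trials, key=lambda t: t[2])
        assert params["C"] == pytest.approx(10.0 ** best[0])
        assert params["penalty"] in ("l1", "l2")
        assert 1e-3 <= params["C"] <= 1e3


class TestExperiments:
    def test_experiment_def_validation(self):
        with pytest.raises(ValueError):
            ExperimentDef("bad", ("age", "height"))
        with pytest.raises(ValueError):
            ExperimentDef("bad", ("age",), occlusion_source="oracle")
        assert EXPERIMENTS["lr_5vars_sn"].occlusion_source == "model"

    def test_sign_recovery_on_synthetic_cohort(self):
        # generator signs: higher age/nihss/glucose/occlusion worsen outcome,
        # higher aspects improves it
        cohort, truth = gen_cohort(CohortSpec(n=400, seed=5, missing_rate=0.0))
        cohort = clean_cohort(cohort)
        res = run_lr_experiment("lr_5vars", cohort, k=5, seed=0, budget=4)
        mean_coef = np.mean(res.fold_coefficients, axis=0)
        signs = dict(zip(res.variable_names, np.sign(mean_coef)))
        assert signs["age"] > 0 and signs["nihss"] > 0
        assert signs["aspects"] < 0
        assert res.fold_aucs().mean() > 0.65

    def test_folds_partition_and_metadata(self):
        cohort, _ = gen_cohort(CohortSpec(n=250, seed=6, missing_rate=0.0))
        cohort = clean_cohort(cohort)
        res = run_lr_experiment("lr_2vars", cohort, k=5, seed=1, budget=2)
        assert len(res.records) == 5
        assert len(res.fold_coefficients) == 5
        assert all(c.shape == (2,) for c in res.fold_coefficients)
        assert all(set(p) == {"C", "penalty"} for p in res.fold_params)

    def test_astral_experiment_runs_without_coefficients(self):
        cohort, _ = gen_cohort(CohortSpec(n=250, seed=6, missing_rate=0.0))
        cohort = clean_cohort(cohort)
        res = run_lr_experiment("astral", cohort, k=5, seed=1)
        assert len(res.records) == 5 and res.fold_coefficients == []
        assert res.fold_aucs().mean() > 0.6

    def test_model_occlusion_source_requires_values(self):
        cohort, _ = gen_cohort(CohortSpec(n=200, seed=7, missing_rate=0.0))
        cohort = clean_cohort(cohort)
        with pytest.raises(ValueError):
            run_lr_experiment("lr_5vars_sn", cohort, k=5, budget=2)
        with pytest.raises(ValueError):
            run_lr_experiment("lr_5vars_sn", cohort, k=5, budget=2,
                              occlusion_model_values=np.ones(3))

    def test_comparison_report_shapes(self):
        cohort, _ = gen_cohort(CohortSpec(n=250, seed=8, missing_rate=0.0))
        cohort = clean_cohort(cohort)
        results = {
            "astral": run_lr_experiment("astral", cohort, k=5, seed=0),
            "lr_2vars": run_lr_experiment("lr_2vars", cohort, k=5, seed=0,
                                          budget=2),
        }
        metrics, ttests = comparison_report(results)
        assert list(metrics["experiment"]) == ["astral", "lr_2vars"]
        assert len(ttests) == 1
        row = ttests.iloc[0]
        assert 0.0 <= row["p_value"] <= 1.0
        assert row["direction"] in ("a_higher", "b_higher", "equal")
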
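import numpy as np
import pandas as pd
import pytest

from radrecon import (
    DoseReconstruction,
    aicc,
    evaluate_reconstruction,
    fit_standard_curve,
    predict_dose,
    reconstruct_doses,
    select_model_structure,
    summarize_by_dose,
)

# printed calibration constants reused as convenient test inputs
K_OLS = (-0.43, 2.63, 0.16)
K_ROBUST = (-0.10, 1.36, 0.45)


def eq1(S, k):
    S = np.asarray(S, dtype=float)
    return k[0] + k[1] * S + k[2] * S**4


class TestFit:
    def test_noiseless_exact_recovery(self):
        S = np.linspace(0, 1.8, 25)
        model = fit_standard_curve(S, eq1(S, K_OLS), powers=(1, 4), variant="ols")
        assert np.allclose(model.params, K_OLS, atol=1e-8)

    def test_duplicating_points_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(0, 1.8, 30)
        d = eq1(S, K_OLS) + rng.normal(0, 0.3, 30)
        m1 = fit_standard_curve(S, d, variant="ols")
        m2 = fit_standard_curve(np.tile(S, 2), np.tile(d, 2), variant="ols")
        assert np.allclose(m1.params, m2.params, atol=1e-10)
        m1r = fit_standard_curve(S, d, variant="robust")
        m2r = fit_standard_curve(np.tile(S, 2), np.tile(d, 2), variant="robust")
        assert np.allclose(m1r.params, m2r.params, atol=1e-6)

    def test_robust_beats_ols_under_gross_outlier(self):
        rng = np.random.default_rng(1)
        truth = np.asarray(K_OLS)
        wins = 0
        for _ in range(100):
            S = rng.uniform(0, 1.8, 40)
            d = eq1(S, truth) + rng.normal(0, 0.2, 40)
            d[0] += 15.0  # gross outlier
            ols = fit_standard_curve(S, d, variant="ols")
            rob = fit_standard_curve(S, d, variant="robust")
            if np.linalg.norm(rob.params - truth) < np.linalg.norm(ols.params - truth):
                wins += 1
        assert wins >= 90

    def test_robust_and_ols_agree_on_clean_data(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            S = rng.uniform(0, 1.8, 50)
            d = eq1(S, K_OLS) + rng.normal(0, 0.3, 50)
            ols = fit_standard_curve(S, d, variant="ols")
            rob = fit_standard_curve(S, d, variant="robust")
            assert np.all(np.abs(rob.params - ols.params) < 2 * ols.ses)

    def test_constant_s_rank_deficient(self):
        with pytest.raises(ValueError, match="rank"):
            fit_standard_curve(np.ones(10), np.arange(10.0))


class TestAicc:
    def test_hand_evaluated_toy(self):
        # rss=1, n=10, 3 regression params (+1 variance): p=4
        expected = 10 * np.log(1 / 10) + 2 * 4 + 2 * 4 * 5 / (10 - 4 - 1)
        assert aicc(1.0, 10, 3) == pytest.approx(expected)

    def test_lower_rss_lowers_aicc(self):
        assert aicc(0.5, 20, 3) < aicc(1.0, 20, 3)

    def test_correction_vanishes_for_large_n(self):
        n = 10**6
        aic = n * np.log(1.0 / n) + 2 * 4
        assert aicc(1.0, n, 3) == pytest.approx(aic, abs=1e-3)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 4)


class TestStructureSelection:
    def test_single_candidate_returned_unconditionally(self):
        S = np.linspace(0, 1.8, 20)
        model, table = select_model_structure(S, eq1(S, K_OLS), ((1, 2),))
        assert model.powers == (1, 2)
        assert len(table) == 1

    def test_linear_data_selects_linear_structure(self):
        # the small-sample correction must suppress spurious extra terms
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            S = rng.uniform(0, 2.1, 25)
            d = 0.5 + 2.0 * S + rng.normal(0, 0.3, 25)
            model, _ = select_model_structure(S, d)
            hits += model.powers == (1,)
        assert hits >= 40

    def test_quartic_data_selects_quartic_structure(self):
        # consistency regime: the S**4 term is resolvable from S**3 once n
        # is large enough relative to the noise
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            S = rng.uniform(0, 2.1, 200)
            d = eq1(S, K_OLS) + rng.normal(0, 0.3, 200)
            model, _ = select_model_structure(S, d)
            hits += model.powers == (1, 4)
        assert hits >= 40


class TestPrediction:
    @pytest.mark.parametrize(
        "k,S,expected",
        [
            (K_OLS, 0.0, -0.43),
            (K_ROBUST, 0.0, -0.10),
            (K_ROBUST, 1.0, 1.71),
        ],
    )
    def test_printed_parameter_arithmetic(self, k, S, expected):
        from radrecon.curve import StandardCurveModel

        model = StandardCurveModel(
            variant="ols", powers=(1, 4), params=np.array(k),
            ses=np.zeros(3), n_train=0, aicc=np.nan, rss=np.nan,
        )
        assert predict_dose(model, [S])[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_s_for_positive_coefficients(self):
        from radrecon.curve import StandardCurveModel

        model = StandardCurveModel(
            variant="ols", powers=(1, 4), params=np.array([-0.4, 2.6, 0.2]),
            ses=np.zeros(3), n_train=0, aicc=np.nan, rss=np.nan,
        )
        S = np.linspace(0, 3, 200)
        assert np.all(np.diff(model.predict(S)) > 0)


class TestEvaluation:
    def test_perfect_prediction(self):
        r2, rmse = evaluate_reconstruction([0, 1, 2], [0, 1, 2])
        assert (r2, rmse) == (1.0, 0.0)

    def test_constant_predictor_at_mean_scores_zero(self):
        r2, _ = evaluate_reconstruction([0, 2, 4], [2, 2, 2])
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r2, rmse = evaluate_reconstruction([0, 2, 4], [0, 3, 4])
        assert rmse == pytest.approx(np.sqrt(1 / 3))
        assert r2 == pytest.approx(7 / 8)

    def test_constant_truth_flagged(self):
        r2, rmse = evaluate_reconstruction([2, 2, 2], [1, 2, 3])
        assert np.isnan(r2) and rmse > 0


class TestSummary:
    def _recon(self, true, est):
        frame = pd.DataFrame(
            {"true_dose_gy": true, "estimated_dose_gy": est},
            index=pd.Index([f"s{i}" for i in range(len(true))], name="sample_id"),
        )
        return DoseReconstruction(per_sample=frame, r2=np.nan, rmse=np.nan)

    def test_group_stats(self):
        table = summarize_by_dose(self._recon([0, 0, 2, 2, 4], [1.0, 3.0, 2.0, 2.0, 5.0]))
        assert len(table) == 3
        row0 = table[table["true_dose_gy"] == 0].iloc[0]
        assert row0["mean"] == 2.0 and row0["sd"] == pytest.approx(np.sqrt(2))
        row2 = table[table["true_dose_gy"] == 2].iloc[0]
        assert row2["sd"] == 0.0

    def test_singleton_group_sd_undefined(self):
        table = summarize_by_dose(self._recon([0, 1], [0.1, 0.9]))
        assert table["sd"].isna().all()
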
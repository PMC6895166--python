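import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radrecon import (
    SimulationConfig,
    compute_normalized_signal,
    generate_study,
    build_signature,
    median_signature_signal,
    merge_datasets,
    preprocess,
    score_normalizer_candidates,
    select_normalizers,
)

from conftest import make_dataset


def _two_dataset_pool(values, doses, genes=None):
    n = len(doses)
    half = n // 2
    a = make_dataset(values[:, :half], doses=doses[:half], dataset_id="A", genes=genes)
    b = make_dataset(values[:, half:], doses=doses[half:], dataset_id="B", genes=genes)
    b.values.columns = [f"t{i}" for i in range(n - half)]
    b.sample_meta.index = pd.Index(b.values.columns, name="sample_id")
    return merge_datasets([a, b])


class TestScoring:
    def test_hand_computed_ssd(self):
        # signature gene s1 defines the median; candidate c has (5,7) in the
        # two controls vs signature medians (4,9): ssd = 1 + 4 = 5
        values = np.array(
            [
                [4.0, 1.0, 9.0, 2.0],   # sig (controls are cols 0 and 2)
                [5.0, 0.0, 7.0, 0.0],   # candidate c
            ]
        )
        pooled = _two_dataset_pool(values, doses=[0, 2, 0, 2], genes=["sig", "c"])
        scores = score_normalizer_candidates(pooled, ["sig"])
        assert scores.loc["c", "ssd_control"] == pytest.approx(5.0)

    def test_candidate_equal_to_signature_median_scores_zero(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(8, 1, (3, 8))
        med = np.median(sig, axis=0)
        values = np.vstack([sig, med[None, :]])
        pooled = _two_dataset_pool(values, doses=[0, 1, 2, 0, 0, 1, 2, 0],
                                   genes=["s1", "s2", "s3", "cand"])
        scores = score_normalizer_candidates(pooled, ["s1", "s2", "s3"])
        assert scores.loc["cand", "ssd_control"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_controls_in_one_dataset_rejected(self):
        values = np.random.default_rng(1).normal(size=(3, 4))
        pooled = _two_dataset_pool(values, doses=[0, 2, 1, 2])
        with pytest.raises(ValueError, match="B"):
            score_normalizer_candidates(pooled, [pooled.gene_ids[0]])


class TestSelection:
    def _scores(self, ssd, rho, p):
        return pd.DataFrame(
            {"ssd_control": ssd, "abs_rho_dose": rho, "rho_p": p},
            index=[f"g{i}" for i in range(len(ssd))],
        )

    def test_smaller_ssd_wins_at_equal_rho(self):
        scores = self._scores([50.0, 5.0], [0.05, 0.05], [0.8, 0.8])
        sel = select_normalizers(scores, target_size=1)
        assert sel.gene_ids == ["g1"]

    def test_dose_responsive_candidate_never_beats_eligible_one(self):
        scores = self._scores([1.0, 5.0], [0.9, 0.02], [1e-9, 0.9])
        sel = select_normalizers(scores, target_size=1)
        assert sel.gene_ids == ["g1"]

    def test_fixed_cutoff_mode(self):
        scores = self._scores([1.0, 5.0], [0.3, 0.05], [0.2, 0.9])
        sel = select_normalizers(scores, target_size=1, rho_cutoff=0.1)
        assert sel.gene_ids == ["g1"]

    def test_rank_sum_fallback_fills_and_flags(self):
        scores = self._scores([1.0, 2.0, 3.0], [0.02, 0.5, 0.9], [0.9, 1e-4, 1e-9])
        sel = select_normalizers(scores, target_size=2)
        assert sel.relaxed
        assert sel.gene_ids[0] == "g0" and len(sel) == 2

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_normalizers(pd.DataFrame(columns=["ssd_control", "abs_rho_dose"]), 5)


class TestNormalizedSignal:
    def test_equal_medians_give_zero(self, toy_dataset):
        s = compute_normalized_signal(toy_dataset, ["g0", "g1"], ["g0", "g1"])
        assert np.allclose(s.s, 0.0)

    def test_shift_invariance_exact(self, toy_dataset):
        shifted = toy_dataset.copy()
        shifted.values["s3"] += 3.0
        a = compute_normalized_signal(toy_dataset, ["g0", "g1"], ["g4", "g5"])
        b = compute_normalized_signal(shifted, ["g0", "g1"], ["g4", "g5"])
        assert np.allclose(a.s, b.s, atol=1e-12)

    def test_random_per_sample_offsets_leave_s_unchanged(self, toy_dataset):
        rng = np.random.default_rng(2)
        shifted = toy_dataset.copy()
        shifted.values.iloc[:, :] += rng.normal(0, 5, toy_dataset.n_samples)[None, :]
        a = compute_normalized_signal(toy_dataset, ["g0", "g1", "g2"], ["g3", "g4"])
        b = compute_normalized_signal(shifted, ["g0", "g1", "g2"], ["g3", "g4"])
        assert np.allclose(a.s, b.s, atol=1e-10)

    def test_low_coverage_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="coverage"):
            compute_normalized_signal(toy_dataset, ["g0", "nope1", "nope2"], ["g4"])


@pytest.fixture(scope="module")
def analyzed_study():
    datasets, truth = generate_study(SimulationConfig(n_genes=1500), seed=51)
    prep = {k: preprocess(v) for k, v in datasets.items()}
    sig, _ = build_signature(prep["train1"], seed=51)
    pooled = merge_datasets([prep["train1"], prep["train2"]])
    scores = score_normalizer_candidates(pooled, sig)
    norm = select_normalizers(scores, target_size=len(sig))
    return truth, pooled, sig, scores, norm


def test_planted_normalizers_rank_in_best_decile(analyzed_study):
    truth, pooled, sig, scores, _ = analyzed_study
    ranks = scores["ssd_control"].rank() / len(scores)
    planted = [g for g in truth.normalizers if g in scores.index]
    assert (ranks.loc[planted] <= 0.10).mean() >= 0.8


def test_selected_set_is_mostly_planted(analyzed_study):
    truth, _, _, _, norm = analyzed_study
    frac = len(set(norm.gene_ids) & set(truth.normalizers)) / len(norm)
    assert frac >= 0.8


def test_normalization_improves_pooled_dose_correlation(analyzed_study):
    """Subtracting the normalizer median must beat the raw signature median
    when baselines shift between datasets."""
    truth, pooled, sig, _, norm = analyzed_study
    s = compute_normalized_signal(pooled, sig, norm)
    dose = pooled.dose_gy.to_numpy()
    rho_s = stats.spearmanr(s.s.to_numpy(), dose).statistic
    rho_raw = stats.spearmanr(
        median_signature_signal(pooled, sig.gene_ids).to_numpy(), dose
    ).statistic
    assert rho_s > 0.9
    assert abs(rho_s) >= abs(rho_raw)
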
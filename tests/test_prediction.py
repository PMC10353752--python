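import hashlib

import numpy as np
import pytest

from arcsync.arc import PhaseSegmentation
from arcsync.prediction import (
    FeatureTensor,
    engagement_at_windows,
    loo_predict,
    per_phase_prediction,
    permutation_null_prediction,
    proportion_scores,
    select_features,
)


def make_tensor(rng, n_sub=5, n_win=60, n_feat=6, labels=None):
    V = rng.standard_normal((n_sub, n_win, n_feat))
    labels = labels or [f"f{i}" for i in range(n_feat)]
    centers = np.arange(n_win) * 0.5
    return FeatureTensor(V, labels, centers)


class TestSelectFeatures:
    def test_injected_engagement_selected_positive(self, rng):
        eng = np.cumsum(rng.standard_normal(80))
        V = rng.standard_normal((5, 80, 4))
        V[:, :, 2] = eng + 0.1 * rng.standard_normal((5, 80))
        idx, signs = select_features(V, eng)
        assert 2 in idx
        assert signs[list(idx).index(2)] > 0

    def test_negated_engagement_selected_negative(self, rng):
        eng = np.cumsum(rng.standard_normal(80))
        V = rng.standard_normal((5, 80, 4))
        V[:, :, 1] = -eng + 0.1 * rng.standard_normal((5, 80))
        sel = select_features(V, eng, feature_labels=["a", "b", "c", "d"])
        assert sel.get("b") == -1

    def test_noise_selection_rate_near_alpha(self, rng):
        eng = rng.standard_normal(50)
        n_feat = 800
        V = rng.standard_normal((6, 50, n_feat))
        idx, _ = select_features(V, eng, alpha=0.05)
        frac = len(idx) / n_feat
        assert 0.02 < frac < 0.09  # binomial neighbourhood of the nominal 0.05


class TestLooPredict:
    def test_oracle_feature_gives_near_perfect_prediction(self, rng):
        eng = np.sin(np.linspace(0, 6 * np.pi, 100))
        tensor = make_tensor(rng, n_sub=4, n_win=100, n_feat=5)
        tensor.values[:, :, 0] = eng
        res = loo_predict(tensor, eng, select="off")
        assert res.mean_r > 0.95

    def test_uninformative_features_centre_on_zero(self):
        rs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            eng = np.sin(np.linspace(0, 4 * np.pi, 60))
            tensor = make_tensor(rng, n_sub=4, n_win=60, n_feat=4)
            rs.append(loo_predict(tensor, eng, select="off").mean_r)
        assert abs(np.mean(rs)) < 2 * np.std(rs) / np.sqrt(len(rs)) + 0.1

    def test_affine_engagement_invariance(self, rng):
        eng = np.sin(np.linspace(0, 4 * np.pi, 60))
        tensor = make_tensor(rng, n_sub=4, n_win=60)
        a = loo_predict(tensor, eng, select="off")
        b = loo_predict(tensor, 5.0 * eng - 3.0, select="off")
        assert np.allclose(a.fold_r, b.fold_r, atol=1e-9)

    def test_determinism(self, rng):
        eng = np.cumsum(rng.standard_normal(60))
        tensor = make_tensor(rng)
        a = loo_predict(tensor, eng)
        b = loo_predict(tensor, eng)
        assert np.array_equal(a.fold_r, b.fold_r)

    def test_selection_sees_only_training_subjects(self, rng):
        """Held-out data must be byte-identical before and after selection+fit."""
        eng = np.cumsum(rng.standard_normal(60))
        tensor = make_tensor(rng)
        held_hash = hashlib.sha256(tensor.values[0].tobytes()).hexdigest()
        loo_predict(tensor, eng, select="on")
        assert hashlib.sha256(tensor.values[0].tobytes()).hexdigest() == held_hash

    def test_too_few_subjects_rejected(self, rng):
        tensor = make_tensor(rng, n_sub=2)
        with pytest.raises(ValueError):
            loo_predict(tensor, np.arange(60.0))


class TestPermutationNull:
    def test_oracle_feature_minimal_p(self, rng):
        eng = np.sin(np.linspace(0, 6 * np.pi, 80))
        tensor = make_tensor(rng, n_sub=4, n_win=80)
        tensor.values[:, :, 0] = eng
        res = permutation_null_prediction(tensor, eng, n_perm=19, seed=0, select="off")
        assert res.permutation.p == pytest.approx(1 / 20)

    def test_p_bounds(self, rng):
        eng = np.cumsum(rng.standard_normal(50))
        tensor = make_tensor(rng, n_win=50)
        res = permutation_null_prediction(
            tensor, eng, n_perm=9, seed=1, select="off", fast_null_windows=30
        )
        assert 1 / 10 <= res.permutation.p <= 1.0


class TestProportionScores:
    def test_exclusive_within_region_selection(self):
        labels = ["F1-F2", "F1-F3", "F2-F3", "F1-C1", "C1-C2"]
        region = {"F1": "F", "F2": "F", "F3": "F", "C1": "C", "C2": "C"}
        loo = type("L", (), {})()
        loo.selected_features_per_fold = [
            {"F1-F2": 1, "F1-F3": 1, "F2-F3": 1} for _ in range(4)
        ]
        scores = proportion_scores(loo, labels, region, n_perm=99, seed=0)
        by_unit = {s.unit: s for s in scores}
        assert by_unit["F-F"].score == pytest.approx(1.0)
        assert by_unit["C-C"].score == 0.0
        assert by_unit["C-F"].score == 0.0
        assert by_unit["F-F"].p == pytest.approx(1 / 100)

    def test_block_sizes_partition_feature_count(self):
        labels = [f"a{i}-b{j}" for i in range(3) for j in range(3)]
        region = {f"a{i}": "F" for i in range(3)} | {f"b{j}": "C" for j in range(3)}
        loo = type("L", (), {})()
        loo.selected_features_per_fold = [{}]
        scores = proportion_scores(loo, labels, region, n_perm=9, seed=0)
        assert sum(s.possible for s in scores) == len(labels)


class TestPerPhase:
    def test_constant_engagement_phase_skipped(self, rng):
        tensor = make_tensor(rng, n_win=60)  # centers 0..29.5 s
        eng = np.cumsum(rng.standard_normal(60))
        eng[:20] = 2.0  # first phase constant
        seg = PhaseSegmentation(names=("a", "b"), starts_s=(0.0, 10.0), end_s=30.0)
        out = per_phase_prediction(
            tensor, eng, seg, n_perm=9, seed=0, select="off", fast_null_windows=30
        )
        assert out["a"] is None
        assert out["b"] is not None
        assert out["b"].permutation.p_fdr is not None

    def test_short_phase_skipped(self, rng):
        tensor = make_tensor(rng, n_win=60)
        eng = np.cumsum(rng.standard_normal(60))
        seg = PhaseSegmentation(names=("a", "b"), starts_s=(0.0, 28.0), end_s=30.0)
        out = per_phase_prediction(tensor, eng, seg, n_perm=9, seed=0, select="off")
        assert out["b"] is None  # only 4 windows fall in [28, 30)


def test_engagement_at_windows_sampling():
    eng = np.arange(100.0)
    vals = engagement_at_windows(eng, fs_hz=10.0, centers_s=[0.0, 5.0, 9.9])
    assert np.allclose(vals, [0.0, 50.0, 99.0])
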
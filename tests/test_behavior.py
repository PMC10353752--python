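import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arcsync.behavior import (
    phase_sd_comparison,
    rating_synchrony,
    recall_similarity,
    resample_ratings,
    segmentation_agreement,
)
from arcsync.synthetic import make_recall_corpus, make_segmentation_raters


class TestResampleRatings:
    def test_staircase_from_integer_second_events(self):
        times = np.arange(9.0)
        values = np.arange(1.0, 10.0)
        trace = resample_ratings(times, values, fs_hz=4.0, duration_s=9.0, znorm=False)
        assert len(trace) == 36
        assert np.array_equal(trace, np.repeat(values, 4))

    def test_samples_before_first_event_take_midpoint(self):
        trace = resample_ratings([2.0], [9.0], fs_hz=2.0, duration_s=4.0, znorm=False)
        assert np.array_equal(trace, [5.0, 5.0, 5.0, 5.0, 9.0, 9.0, 9.0, 9.0])

    def test_attained_values_preserved(self):
        times = [0.0, 1.5, 3.0]
        values = [2.0, 7.0, 4.0]
        trace = resample_ratings(times, values, fs_hz=10.0, duration_s=5.0, znorm=False)
        assert set(np.unique(trace)) == set(values)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            resample_ratings([0.0], [5.0], fs_hz=10.0, duration_s=2.0)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            resample_ratings([], [], fs_hz=10.0, duration_s=2.0)


class TestRatingSynchrony:
    def test_identical_raters_fully_synchronous(self, rng):
        x = np.cumsum(rng.standard_normal(500))
        out = rating_synchrony(np.tile(x, (4, 1)))
        assert out["mean_r"] == pytest.approx(1.0, abs=1e-6)
        assert out["frac_significant_positive"] == 1.0

    def test_twenty_raters_give_190_pairs(self, rng):
        out = rating_synchrony(rng.standard_normal((20, 100)))
        assert out["n_pairs"] == 190

    def test_independent_raters_average_near_zero(self, rng):
        out = rating_synchrony(rng.standard_normal((12, 2000)))
        assert abs(out["mean_r"]) < 0.05

    def test_degenerate_rater_excluded(self, rng):
        mat = rng.standard_normal((4, 100))
        mat[1] = 3.0
        out = rating_synchrony(mat)
        assert out["n_pairs"] == 3  # 3 usable raters


class TestSegmentation:
    def test_identical_stamps_accept_every_boundary(self, template):
        df = make_segmentation_raters(template, 8, 0.0, 0.0, seed=0)
        res = segmentation_agreement(df, template.duration_s, n_shuffles=200, seed=0)
        assert len(res.boundaries) == 6
        assert all(c == 8 for _, c in res.boundaries)
        truth = np.asarray(template.boundaries_s[:-1])
        for t, _ in res.boundaries:
            assert np.min(np.abs(truth - t)) <= res.window_s

    def test_translation_equivariance(self, template):
        df = make_segmentation_raters(template, 8, 2.0, 0.0, seed=1)
        delta = 20.0
        shifted = df.assign(start_s=df["start_s"] + delta)
        a = segmentation_agreement(df, template.duration_s + delta, n_shuffles=150, seed=2)
        b = segmentation_agreement(shifted, template.duration_s + delta, n_shuffles=150, seed=2)
        ta = np.array([t for t, _ in a.boundaries])
        tb = np.array([t for t, _ in b.boundaries])
        assert len(ta) == len(tb)
        assert np.allclose(tb - ta, delta, atol=a.window_s)

    def test_too_few_raters_rejected(self, template):
        df = make_segmentation_raters(template, 3, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            segmentation_agreement(df, template.duration_s)


class TestRecall:
    def test_identical_documents_fully_similar(self):
        docs = {f"s{i}": {"p1": "alpha beta gamma delta epsilon zeta"} for i in range(4)}
        sims = recall_similarity(docs, k=3, min_count=1)
        assert sims["p1"].mean == pytest.approx(1.0, abs=1e-9)
        assert sims["p1"].sd == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_vocabularies_orthogonal(self):
        docs = {
            "s0": {"p1": "aaa bbb ccc aaa bbb ccc"},
            "s1": {"p1": "ddd eee fff ddd eee fff"},
            "s2": {"p1": "aaa bbb ccc aaa bbb ccc"},
        }
        sims = recall_similarity(docs, k=2, min_count=1)
        m = sims["p1"].similarity
        assert abs(m[0, 1]) < 0.2
        assert m[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_length_scaling_invariance(self):
        base = "aaa bbb ccc ddd "
        docs = {
            "s0": {"p1": base * 2},
            "s1": {"p1": base * 10},
            "s2": {"p1": base},
        }
        sims = recall_similarity(docs, k=2, min_count=1)
        iu = np.triu_indices(3, k=1)
        assert np.allclose(sims["p1"].similarity[iu], 1.0, atol=1e-9)

    def test_merge_last_two_phases(self):
        docs = make_recall_corpus(4, 3, 0.8, seed=0)
        sims = recall_similarity(docs, k=5, merge_last_two=True)
        assert list(sims) == ["p1", "p2+p3"]

    def test_high_overlap_phase_has_lowest_sd(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            docs = make_recall_corpus(8, 4, [0.5, 0.5, 0.5, 0.9], seed=seed)
            sims = recall_similarity(docs, k=10)
            sds = {p: s.sd for p, s in sims.items()}
            wins += min(sds, key=sds.get) == "p4"
        assert wins >= 0.8 * n_seeds


class TestPhaseSdComparison:
    def test_identical_groups_give_f_near_zero(self):
        sim = type("S", (), {})
        groups = {}
        base = np.array([0.1, 0.2, 0.15, 0.12, 0.18])
        for p in ("a", "b", "c"):
            s = sim()
            s.subject_sd = base.copy()
            groups[p] = s
        out = phase_sd_comparison(groups)
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert not any(row["significant"] for row in out["pairwise"])

    def test_two_groups_f_equals_t_squared(self, rng):
        sim = type("S", (), {})
        a, b = sim(), sim()
        a.subject_sd = rng.standard_normal(8) + 1.0
        b.subject_sd = rng.standard_normal(8) + 1.5
        out = phase_sd_comparison({"a": a, "b": b})
        t = stats.ttest_ind(a.subject_sd, b.subject_sd, equal_var=True).statistic
        assert out["F"] == pytest.approx(t**2, rel=1e-9)

    def test_shifted_phase_flagged_against_all_others(self, rng):
        sim = type("S", (), {})
        groups = {}
        for p in ("a", "b", "c"):
            s = sim()
            s.subject_sd = rng.standard_normal(10) * 0.05 + 0.5
            groups[p] = s
        low = sim()
        low.subject_sd = rng.standard_normal(10) * 0.05 + 0.2
        groups["d"] = low
        out = phase_sd_comparison(groups)
        flagged = {
            frozenset((row["phase_a"], row["phase_b"]))
            for row in out["pairwise"]
            if row["significant"]
        }
        assert all(frozenset((p, "d")) in flagged for p in ("a", "b", "c"))
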
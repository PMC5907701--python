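"""Precision/recall/F1 at residue and strand level, PR curves."""

import itertools

import numpy as np
import pytest

from betaridge import (
    LabelSet,
    binarize,
    f1_score,
    pr_curve,
    residue_eval,
    ss_profile_from_string,
    strand_eval,
    strands_from_ss,
)


class TestF1Score:
    @pytest.mark.parametrize(
        "p,r,expected_pct",
        [
            # published benchmark rows: (precision, recall) -> printed F1
            (0.6800, 0.5562, 61.19),
            (0.6791, 0.5769, 62.38),
            (0.8102, 0.7101, 75.69),
            (0.7948, 0.7347, 76.36),
            (0.7656, 0.6786, 71.95),
            (0.6503, 0.5599, 60.17),
        ],
    )
    def test_harmonic_mean_reproduces_printed_tables(self, p, r, expected_pct):
        assert round(100 * f1_score(p, r), 2) == pytest.approx(expected_pct, abs=0.005)

    def test_identity_when_equal(self):
        for x in (0.0, 0.25, 0.5, 1.0):
            assert f1_score(x, x) == pytest.approx(x)

    def test_zero_convention(self):
        assert f1_score(0.0, 0.0) == 0.0

    def test_range_check(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)


class TestBinarize:
    def test_toy_map(self):
        m = np.zeros((4, 4))
        m[0, 2] = m[2, 0] = 0.9
        m[1, 3] = m[3, 1] = 0.4
        assert binarize(m, 0.5) == {(0, 2)}

    def test_cutoff_extremes(self):
        m = np.random.default_rng(0).random((5, 5))
        m = 0.5 * (m + m.T)
        assert binarize(m, 0.0) == set(map(tuple, np.column_stack(np.triu_indices(5, 1)).tolist()))
        assert binarize(np.clip(m, 0, 0.8), 0.9) == set()

    def test_triangle_independent(self):
        m = np.zeros((5, 5))
        m[1, 4] = m[4, 1] = 0.7
        assert binarize(m, 0.5) == binarize(m.T, 0.5)


class TestResidueEval:
    def test_perfect_prediction(self):
        truth = LabelSet(contacts={(0, 5), (2, 7)})
        res = residue_eval({(0, 5), (2, 7)}, truth)
        assert res.precision == res.recall == res.f1 == 1.0

    def test_half_right(self):
        truth = LabelSet(contacts={(0, 5), (2, 7)})
        res = residue_eval({(0, 5), (1, 6)}, truth)
        assert (res.tp, res.fp, res.fn) == (1, 1, 1)
        assert res.precision == res.recall == res.f1 == 0.5

    def test_empty_prediction(self):
        truth = LabelSet(contacts={(0, 5)})
        res = residue_eval(set(), truth)
        assert res.precision == res.recall == res.f1 == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            L = int(rng.integers(6, 20))
            univ = list(itertools.combinations(range(L), 2))
            truth_pairs = {univ[k] for k in rng.choice(len(univ), 5, replace=False)}
            pred_pairs = {univ[k] for k in rng.choice(len(univ), 7, replace=False)}
            res = residue_eval(pred_pairs, LabelSet(contacts=truth_pairs))
            tp = sum(1 for p in pred_pairs if p in truth_pairs)
            assert res.tp == tp
            assert res.fp == len(pred_pairs) - tp
            assert res.fn == len(truth_pairs) - tp


class TestStrands:
    def test_run_length_scan(self):
        assert strands_from_ss("CEEECEEC") == [(1, 3), (5, 6)]

    def test_no_strands(self):
        assert strands_from_ss("CCCC") == []

    def test_singleton(self):
        assert strands_from_ss("E") == [(0, 0)]

    def test_soft_profile_rejected(self):
        probs = np.full((4, 3), 1 / 3)
        from betaridge import SecondaryStructureProfile

        with pytest.raises(ValueError):
            strands_from_ss(SecondaryStructureProfile(probs))


class TestStrandEval:
    strands = [(0, 3), (6, 9), (12, 15)]  # A, B, C

    def test_single_pair_makes_strand_pair(self):
        truth = LabelSet(contacts={(0, 7), (1, 6), (2, 9)})
        res = strand_eval({(3, 6)}, truth, self.strands)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_intra_strand_pairs_ignored(self):
        truth = LabelSet(contacts={(0, 7)})
        res = strand_eval({(0, 3), (0, 7)}, truth, self.strands)
        assert res.fp == 0 and res.tp == 1

    def test_counting_example(self):
        truth = LabelSet(contacts={(0, 7)})          # native: (A,B)
        pred = {(1, 8), (7, 13)}                     # predicted: (A,B), (B,C)
        res = strand_eval(pred, truth, self.strands)
        assert res.precision == 0.5
        assert res.recall == 1.0
        assert res.f1 == pytest.approx(2 / 3)

    def test_invariant_to_added_intra_strand_pairs(self):
        truth = LabelSet(contacts={(0, 7), (8, 13)})
        pred = {(1, 8), (9, 14)}
        base = strand_eval(pred, truth, self.strands)
        noisy = strand_eval(pred | {(0, 2), (12, 14)}, truth, self.strands)
        assert (base.tp, base.fp, base.fn) == (noisy.tp, noisy.fp, noisy.fn)

    def test_residue_outside_strands_contributes_nothing(self):
        truth = LabelSet(contacts={(0, 7)})
        res = strand_eval({(4, 8)}, truth, self.strands)  # 4 is coil
        assert res.fp == 0


class TestPRCurve:
    def _map_truth(self, seed=11, L=15):
        rng = np.random.default_rng(seed)
        m = rng.random((L, L))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0)
        truth = LabelSet(contacts={(0, 5), (3, 9), (2, 12)})
        return m, truth

    def test_perfect_predictor_pinned_at_p1(self):
        L = 12
        truth = LabelSet(contacts={(1, 5), (2, 8)})
        m = np.zeros((L, L))
        for i, j in truth.contacts:
            m[i, j] = m[j, i] = 1.0
        curve = pr_curve(m, truth, [0.1, 0.5, 1.0])
        for _, res in curve:
            assert res.precision == 1.0 and res.recall == 1.0

    def test_recall_monotone_nonincreasing(self):
        for seed in (1, 2, 3):
            m, truth = self._map_truth(seed)
            curve = pr_curve(m, truth, list(np.linspace(0, 1, 21)))
            recalls = [res.recall for _, res in curve]
            assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_cutoff_above_one_gives_origin(self):
        m, truth = self._map_truth()
        (_, res), = pr_curve(m, truth, [1.01])
        assert (res.precision, res.recall) == (0.0, 0.0)

    def test_unsorted_grid_rejected(self):
        m, truth = self._map_truth()
        with pytest.raises(ValueError):
            pr_curve(m, truth, [0.5, 0.2])
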
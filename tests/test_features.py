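"""Window masks, candidate enumeration, feature-row assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaridge import (
    ContactMap,
    build_window_mask,
    candidate_pairs,
    extract_pair_features,
    feature_schema,
    map_features,
    position_features,
    ss_profile_from_string,
)
from betaridge.synthetic import corrupt_ss_profile


def brute_force_mask_count(ws: int, dw: int) -> int:
    half = (dw - 1) // 2
    n = 0
    for r in range(ws):
        for c in range(ws):
            if abs(r - c) <= half or abs(r + c - (ws - 1)) <= half:
                n += 1
    return n


class TestWindowMask:
    @pytest.mark.parametrize("ws", [3, 5, 7, 9])
    @pytest.mark.parametrize("dw", [1, 3, 5, 7, 9])
    def test_counts_match_enumeration(self, ws, dw):
        mask = build_window_mask(ws, dw)
        assert mask.n_cells == brute_force_mask_count(ws, dw)

    @pytest.mark.parametrize("ws,dw,count", [(3, 3, 9), (5, 3, 21), (9, 3, 45)])
    def test_spot_values(self, ws, dw, count):
        assert build_window_mask(ws, dw).n_cells == count

    def test_full_square_when_dw_covers(self):
        assert build_window_mask(5, 9).n_cells == 25

    def test_180_degree_symmetry(self):
        for ws, dw in ((5, 3), (9, 3), (7, 5)):
            cells = build_window_mask(ws, dw).cells
            assert np.array_equal(cells, np.rot90(cells, 2))

    def test_even_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_window_mask(4, 3)
        with pytest.raises(ValueError):
            build_window_mask(5, 2)


class TestCandidatePairs:
    def test_enumeration_small(self):
        assert candidate_pairs(5, 3).tolist() == [[0, 3], [0, 4], [1, 4]]

    def test_empty_when_too_short(self):
        assert candidate_pairs(3, 3).size == 0

    def test_closed_form_count(self):
        for L in (5, 12, 30):
            assert len(candidate_pairs(L, 1)) == L * (L - 1) // 2

    def test_lexicographic_order(self):
        pairs = [tuple(p) for p in candidate_pairs(10, 4).tolist()]
        assert pairs == sorted(pairs)


class TestPositionAndMapFeatures:
    def test_terminal_pair(self):
        L = 9
        assert position_features(0, L - 1, L).tolist() == [L - 1, 0, L - 1, L - 1, 0]

    def test_interior_pair(self):
        assert position_features(2, 5, 10).tolist() == [3, 2, 7, 5, 4]

    def test_unordered_pair_rejected(self):
        with pytest.raises(ValueError):
            position_features(5, 2, 10)

    def test_seq_ratio(self):
        cm = ContactMap(np.zeros((100, 100)), n_seqs=500)
        assert map_features(cm)[0] == 5.0

    def test_constant_map_zero_std(self):
        cm = ContactMap(np.full((10, 10), 0.4))
        assert map_features(cm)[1] == pytest.approx(0.0, abs=1e-12)

    def test_std_matches_hand_computation(self):
        m = np.zeros((6, 6))
        vals = {(0, 3): 0.2, (0, 4): 0.8, (0, 5): 0.5, (1, 4): 0.1,
                (1, 5): 0.9, (2, 5): 0.3}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        cm = ContactMap(m)
        assert map_features(cm, min_sep=3)[1] == pytest.approx(
            np.std(list(vals.values()))
        )

    def test_missing_depth_reads_zero(self):
        cm = ContactMap(np.zeros((10, 10)))
        assert map_features(cm)[0] == 0.0


class TestFeatureRows:
    def _inputs(self, L=20, seed=3):
        rng = np.random.default_rng(seed)
        maps = [rng.random((L, L)) for _ in range(3)]
        ss = corrupt_ss_profile("C" * L, accuracy=1.0, seed=seed)
        return maps, ss

    def test_stage1_row_length(self):
        maps, ss = self._inputs()
        mask = build_window_mask(5, 3)
        row = extract_pair_features(maps, ss, np.array([1.0, 0.5]), mask,
                                    np.array([[4, 12]]))
        assert row.shape == (1, 3 * 21 + 2 * 5 * 3 + 5 + 2)
        assert len(feature_schema(("a", "b", "c"), mask, 5)) == row.shape[1]

    def test_boundary_cells_carry_sentinel(self):
        maps, ss = self._inputs()
        L = maps[0].shape[0]
        mask = build_window_mask(5, 5)  # full square so corners are sampled
        row = extract_pair_features(maps, ss, None, mask,
                                    np.array([[0, L - 1]]),
                                    include_position=False)
        map_block = row[0, : 3 * 25].reshape(3, 25)
        offs = mask.offsets
        outside = ((0 + offs[:, 0]) < 0) | ((L - 1 + offs[:, 1]) >= L)
        assert outside.any()
        assert np.all(map_block[:, outside] == -1.0)
        assert np.all(map_block[:, ~outside] != -1.0)

    def test_ss_window_zero_padded(self):
        maps, ss = self._inputs()
        mask = build_window_mask(5, 3)
        row = extract_pair_features(maps, ss, None, mask, np.array([[0, 10]]),
                                    include_position=False)
        ss_block = row[0, 3 * 21: 3 * 21 + 15].reshape(5, 3)
        assert np.all(ss_block[:2] == 0.0)      # residues -2, -1 of the i-window
        assert np.all(ss_block[2:].sum(axis=1) > 0)

    def test_deterministic(self):
        maps, ss = self._inputs()
        mask = build_window_mask(7, 3)
        pairs = candidate_pairs(20, 3)
        a = extract_pair_features(maps, ss, np.array([0.1, 0.2]), mask, pairs)
        b = extract_pair_features(maps, ss, np.array([0.1, 0.2]), mask, pairs)
        assert np.array_equal(a, b)

    def test_disordered_pair_rejected(self):
        maps, ss = self._inputs()
        mask = build_window_mask(3, 3)
        with pytest.raises(ValueError):
            extract_pair_features(maps, ss, None, mask, np.array([[5, 2]]))

    def test_mismatched_map_shapes_rejected(self):
        maps, ss = self._inputs()
        maps[1] = maps[1][:-1, :-1]
        with pytest.raises(ValueError):
            extract_pair_features(maps, ss, None, build_window_mask(3, 3),
                                  np.array([[1, 5]]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    ws=st.sampled_from([3, 5, 7, 9]),
    dw=st.sampled_from([1, 3, 5, 7, 9]),
    n_maps=st.integers(min_value=1, max_value=5),
)
def test_schema_length_formula(ws, dw, n_maps):
    """Row length is a pure function of (n_maps, ws, dw)."""
    mask = build_window_mask(ws, dw)
    names = [f"m{k}" for k in range(n_maps)]
    expected = n_maps * brute_force_mask_count(ws, dw) + 2 * ws * 3 + 5 + 2
    assert len(feature_schema(names, mask, ws)) == expected
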
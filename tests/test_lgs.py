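"""LGS pattern tables, block encoding and sliding-window code matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eeglgs import ConnectivityMatrix, apply_all, apply_lgs, builtin_patterns, encode_block
from eeglgs.exceptions import ContractError
from eeglgs.lgs import LGSPattern, load_patterns, save_patterns
from oracles import naive_lgs_codes

PATTERNS = builtin_patterns()
EXPECTED_BLOCKS = {
    "SLGS": (3, 5), "LELGS": (4, 4), "VLGS": (4, 3), "VSLGS": (5, 3),
    "ZHLGS": (3, 3), "ZHMLGS": (3, 3), "ZVLGS": (3, 3), "ZVMLGS": (3, 3),
}


class TestPatternTables:
    def test_eight_distinct_operators(self):
        names = [p.name for p in PATTERNS]
        assert len(names) == 8
        assert len(set(names)) == 8
        assert set(names) == set(EXPECTED_BLOCKS)

    @pytest.mark.parametrize("pattern", PATTERNS, ids=lambda p: p.name)
    def test_block_shapes_match_published_geometry(self, pattern):
        assert (pattern.block_rows, pattern.block_cols) == EXPECTED_BLOCKS[pattern.name]

    @pytest.mark.parametrize("pattern", PATTERNS, ids=lambda p: p.name)
    def test_exactly_eight_edges_with_unique_bits(self, pattern):
        assert len(pattern.edges) == 8
        positions = [p for _, pos in pattern.groups for p in pos]
        assert sorted(positions) == list(range(8))

    def test_lelgs_is_the_or_combined_operator(self):
        lelgs = {p.name: p for p in PATTERNS}["LELGS"]
        assert lelgs.combine_rule == "bitwise_or"
        assert [len(g[0]) for g in lelgs.groups] == [4, 4]

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "patterns.json"
        save_patterns(PATTERNS, path)
        back = load_patterns(path)
        assert back == PATTERNS


class TestEncodeBlock:
    @pytest.mark.parametrize("pattern", PATTERNS, ids=lambda p: p.name)
    def test_constant_block_codes_255(self, pattern):
        block = np.full((pattern.block_rows, pattern.block_cols), 3.7)
        assert encode_block(block, pattern) == 255

    @pytest.mark.parametrize("name", ["ZHLGS", "ZHMLGS", "ZVLGS", "ZVMLGS"])
    def test_all_ascending_edges_code_0(self, name):
        """Strictly ascending values along a path-like traversal give code 0.

        Only the zigzag operators traverse a simple path; loop-closing
        operators (e.g. SLGS) return to the target, so a fully ascending
        assignment is impossible for them by construction.
        """
        pattern = {p.name: p for p in PATTERNS}[name]
        walk = [pattern.edges[0][0]] + [e[1] for e in pattern.edges]
        assert len(set(walk)) == len(walk)  # simple path
        block = np.zeros((pattern.block_rows, pattern.block_cols))
        for value, (r, c) in enumerate(walk):
            block[r, c] = float(value)
        assert all(block[e[0]] < block[e[1]] for e in pattern.edges)
        assert encode_block(block, pattern) == 0

    @pytest.mark.parametrize("pattern", PATTERNS, ids=lambda p: p.name)
    def test_matches_per_edge_oracle(self, pattern, rng):
        for _ in range(200):
            block = rng.integers(0, 10, size=(pattern.block_rows, pattern.block_cols))
            expected = naive_lgs_codes(block, pattern)[0, 0]
            assert encode_block(block, pattern) == expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            encode_block(np.zeros((2, 2)), PATTERNS[0])

    def test_bit_order_flag_reverses_bits(self, rng):
        pattern = {p.name: p for p in PATTERNS}["ZHLGS"]
        block = rng.standard_normal((3, 3))
        msb = encode_block(block, pattern, bit_order="msb")
        lsb = encode_block(block, pattern, bit_order="lsb")
        assert lsb == int(f"{msb:08b}"[::-1], 2)


class TestApplyLGS:
    def test_19x19_output_shapes(self, rng):
        X = rng.standard_normal((19, 19))
        for pattern in PATTERNS:
            cm = apply_lgs(X, pattern)
            assert cm.codes.shape == (
                19 - pattern.block_rows + 1,
                19 - pattern.block_cols + 1,
            )
        slgs = {p.name: p for p in PATTERNS}["SLGS"]
        assert apply_lgs(X, slgs).codes.shape == (17, 15)
        zh = {p.name: p for p in PATTERNS}["ZHLGS"]
        assert apply_lgs(X, zh).codes.shape == (17, 17)

    def test_constant_matrix_codes_255(self):
        X = np.full((19, 19), 2.0)
        for pattern in PATTERNS:
            assert np.all(apply_lgs(X, pattern).codes == 255)

    @pytest.mark.parametrize("pattern", PATTERNS, ids=lambda p: p.name)
    def test_vectorized_matches_naive_oracle(self, pattern, rng):
        """Optimized sliding encoder is exactly the per-window reference."""
        for _ in range(100):
            X = rng.standard_normal((19, 19))
            assert np.array_equal(apply_lgs(X, pattern).codes, naive_lgs_codes(X, pattern))

    def test_binary_input_codes_in_range(self, rng):
        X = rng.integers(0, 2, size=(19, 19)).astype(float)
        np.fill_diagonal(X, 0)
        cm = ConnectivityMatrix(X, binary=True)
        for code in apply_all(cm):
            assert code.codes.min() >= 0 and code.codes.max() <= 255

    def test_matrix_smaller_than_block_rejected(self):
        slgs = {p.name: p for p in PATTERNS}["SLGS"]
        with pytest.raises(ContractError):
            apply_lgs(np.zeros((3, 4)), slgs)

    def test_apply_all_canonical_order(self, rng):
        X = rng.standard_normal((19, 19))
        names = [c.operator for c in apply_all(X)]
        assert names == sorted(names)
        assert len(names) == 8
        # registration order must not matter
        shuffled = apply_all(X, patterns=tuple(reversed(PATTERNS)))
        assert [c.operator for c in shuffled] == names


class TestInvariances:
    @given(
        scale=st.floats(min_value=0.1, max_value=50.0),
        shift=st.floats(min_value=-100.0, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_and_shift_invariance(self, scale, shift, seed):
        """Codes depend only on pairwise order, so any strictly increasing
        affine transform of the matrix leaves every code unchanged."""
        X = np.random.default_rng(seed).standard_normal((12, 12))
        for pattern in PATTERNS:
            base = apply_lgs(X, pattern).codes
            assert np.array_equal(apply_lgs(X * scale + shift, pattern).codes, base)
            assert np.array_equal(apply_lgs(np.tanh(X) * scale, pattern).codes, base)
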
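"""Unit and property tests for the MIC_e/TIC_e kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micscreen import (
    MineParams,
    characteristic_matrix,
    equicharclump,
    equipartition,
    grid_bound,
    mic_e,
    optimize_axis,
    tic_e,
)
from oracle_mine import brute_equipartition, oracle_char_matrix

DEFAULTS = MineParams()


class TestGridBound:
    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(100, 0.75, 31), (2, 0.85, 4), (10_000, 0.50, 100)],
    )
    def test_values(self, n, alpha, expected):
        assert grid_bound(n, alpha) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            grid_bound(1, 0.75)
        with pytest.raises(ValueError):
            grid_bound(100, 0.0)


class TestEquipartition:
    @pytest.mark.parametrize(
        "values, l, sizes",
        [
            (np.arange(6.0), 3, (2, 2, 2)),
            (np.arange(10.0), 3, (4, 3, 3)),  # remainder to low rows
            (np.array([1.0, 1.0, 1.0, 2.0]), 2, (3, 1)),  # ties cohere
        ],
    )
    def test_sizes(self, values, l, sizes):
        rows = equipartition(values, l)
        assert tuple(np.bincount(rows, minlength=l)) == sizes

    def test_ties_share_row(self):
        values = np.array([3.0, 1.0, 3.0, 2.0, 3.0, 0.0])
        rows = equipartition(values, 3)
        tied = rows[values == 3.0]
        assert len(set(tied)) == 1

    @given(
        data=st.lists(st.integers(0, 5), min_size=4, max_size=30),
        l=st.integers(2, 4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_balance_and_order_dependence_only(self, data, l):
        values = np.asarray(data, dtype=float)
        if len(values) < l:
            return
        rows = equipartition(values, l)
        # depends only on sort order: a strictly increasing transform
        # leaves the assignment unchanged
        assert np.array_equal(rows, equipartition(np.exp(values), l))
        # tie cohesion
        for v in np.unique(values):
            assert len(set(rows[values == v])) == 1
        # with all-distinct values, masses are balanced within 1
        if len(np.unique(values)) == len(values):
            counts = np.bincount(rows, minlength=l)
            assert counts.max() - counts.min() <= 1


class TestEquicharclump:
    def test_monotone_two_rows(self):
        x = np.arange(10.0)
        rows = equipartition(x, 2)  # y = x
        assert list(equicharclump(x, rows, max_clumps=20)) == [5, 10]

    def test_alternating_superclumps(self):
        x = np.arange(8.0)
        rows = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        bounds = equicharclump(x, rows, max_clumps=4)
        assert list(bounds) == [2, 4, 6, 8]  # near-equal mass merging

    def test_noop_when_under_limit(self):
        x = np.arange(8.0)
        rows = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert list(equicharclump(x, rows, max_clumps=8)) == list(range(1, 9))


class TestOptimizeAxis:
    def test_monotone_reaches_row_entropy(self):
        x = np.arange(12.0)
        rows = equipartition(x, 2)
        prof = optimize_axis(x, rows, k_max=4)
        assert prof == pytest.approx([1.0, 1.0, 1.0])  # H(rows) = 1 bit

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.uniform(size=8)
            rows = brute_equipartition(rng.uniform(size=8), 2)
            prof = optimize_axis(x, rows, k_max=3)
            from oracle_mine import _best_mi_over_cuts

            expected = [_best_mi_over_cuts(x, rows, k) for k in (2, 3)]
            assert prof == pytest.approx(expected, abs=1e-12)
            assert prof[1] >= prof[0] - 1e-12  # non-decreasing in k

    def test_independent_blocks_zero(self):
        # rows identical within every column -> factorizing counts
        x = np.arange(8.0)
        rows = np.zeros(8, dtype=int)
        prof = optimize_axis(x, rows, k_max=3)
        assert prof == pytest.approx([0.0, 0.0])

    def test_invalid_kmax(self):
        with pytest.raises(ValueError):
            optimize_axis(np.arange(5.0), np.zeros(5, dtype=int), k_max=1)


class TestCharacteristicMatrix:
    def test_identity_b4(self):
        x = np.arange(10.0)
        cm = characteristic_matrix(x, x, MineParams(b=4))
        assert cm.entries == {(2, 2): 1.0}

    def test_constant_vector_zero_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="constant"):
            cm = characteristic_matrix(x, np.ones(10))
        assert all(v == 0.0 for v in cm.entries.values())

    def test_entry_set_and_bounds(self):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(size=50), rng.uniform(size=50)
        cm = characteristic_matrix(x, y, DEFAULTS)
        expected_keys = {
            (k, l)
            for k in range(2, 5)
            for l in range(2, 5)
            if k * l <= 9
        }
        assert set(cm.entries) == expected_keys
        assert all(0.0 <= v <= 1.0 for v in cm.entries.values())

    def test_non_finite_rejected(self):
        x = np.arange(10.0)
        y = x.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            characteristic_matrix(x, y)

    def test_oracle_equivalence_small_instances(self):
        """Exhaustive-search equality on n <= 10, B <= 8 (clump limit inactive)."""
        rng = np.random.default_rng(42)
        cases = []
        for n in (5, 7, 8, 10):
            for b in (4, 6, 8):
                cases.append((rng.uniform(size=n), rng.uniform(size=n), b))
        # tied-value instances
        cases.append((np.array([1.0, 1, 2, 2, 3, 3, 4]), rng.uniform(size=7), 6))
        cases.append(
            (rng.integers(0, 3, size=9).astype(float),
             rng.integers(0, 4, size=9).astype(float), 8)
        )
        for x, y, b in cases:
            expected = oracle_char_matrix(x, y, b)
            cm = characteristic_matrix(x, y, MineParams(b=b))
            for key in expected:
                assert cm.entries[key] == pytest.approx(
                    expected[key], abs=1e-12
                ), (key, b, x, y)
            assert mic_e(x, y, MineParams(b=b)) == pytest.approx(
                max(expected.values()), abs=1e-12
            )
            assert tic_e(x, y, MineParams(b=b)) == pytest.approx(
                sum(expected.values()), abs=1e-12
            )


class TestMicTic:
    def test_noiseless_line_saturates(self):
        x = np.linspace(0, 1, 100)
        assert mic_e(x, 3 * x + 7) >= 0.99

    def test_independent_small_and_decreasing(self):
        rng = np.random.default_rng(1)
        vals = {}
        for n in (100, 1000):
            m = np.mean(
                [
                    mic_e(rng.uniform(size=n), rng.uniform(size=n))
                    for _ in range(10)
                ]
            )
            vals[n] = m
        assert vals[1000] < vals[100] < 0.5

    def test_tic_bounded_by_entry_count(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(size=30), rng.uniform(size=30)
        n_entries = len(characteristic_matrix(x, y, DEFAULTS).entries)
        assert 0.0 <= tic_e(x, y, DEFAULTS) <= n_entries

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetry_and_rank_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(size=40), rng.normal(size=40)
        assert mic_e(x, y) == mic_e(y, x)
        assert tic_e(x, y) == tic_e(y, x)
        # strictly increasing transforms leave both statistics unchanged
        gx = np.exp(3.0 * x) - 1.0
        hy = y ** 3 + 5.0 * y
        assert mic_e(gx, hy) == mic_e(x, y)
        assert tic_e(gx, hy) == tic_e(x, y)

    def test_determinism(self):
        rng = np.random.default_rng(11)
        x, y = rng.uniform(size=60), rng.uniform(size=60)
        assert mic_e(x, y) == mic_e(x.copy(), y.copy())
        assert tic_e(x, y) == tic_e(x.copy(), y.copy())

    def test_kernel_matches_python_building_blocks(self):
        """The fused compiled path equals equipartition+clump+DP done in Python."""
        rng = np.random.default_rng(17)
        x, y = rng.uniform(size=60), rng.uniform(size=60)
        b, c = 9, 5
        cm = characteristic_matrix(x, y, MineParams(b=b, c=c))
        for (k, l), entry in cm.entries.items():
            vals = []
            for opt, equi in ((x, y), (y, x)):
                rows = equipartition(equi, l)
                bounds = equicharclump(x=opt, rows=rows,
                                       max_clumps=c * (b // l))
                vals.append(optimize_axis(opt, rows, b // l, bounds)[k - 2])
            assert entry == pytest.approx(
                max(vals) / np.log2(min(k, l)), abs=1e-12
            )
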
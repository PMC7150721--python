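"""Exact ordered clustering: DP vs exhaustive oracle, identities, k selection."""

from __future__ import annotations

import numpy as np
import pytest

from ripart.segmentation import (
    brute_force_segmentation,
    class_diameter,
    count_partitions,
    optimal_segmentation,
    pairwise_diameters,
    select_k,
    slope_curve,
)


class TestCountPartitions:
    @pytest.mark.parametrize("n,k,expected", [(17, 3, 120), (6, 3, 10), (9, 1, 1), (5, 5, 1)])
    def test_values(self, n, k, expected):
        assert count_partitions(n, k) == expected

    @pytest.mark.parametrize("n,k", [(4, 5), (4, 0)])
    def test_domain_errors(self, n, k):
        with pytest.raises(ValueError):
            count_partitions(n, k)


class TestClassDiameter:
    def test_singleton_is_zero(self, rng):
        x = rng.normal(size=(6, 3))
        assert class_diameter(x, 4, 4) == 0.0

    def test_identical_rows_zero(self):
        x = np.ones((4, 2))
        assert class_diameter(x, 1, 4) == 0.0

    def test_direct_arithmetic(self):
        assert class_diameter(np.array([0.0, 2.0]), 1, 2) == pytest.approx(2.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            class_diameter(np.zeros((5, 2)), 3, 2)

    def test_cached_table_matches_direct_summation(self, rng):
        x = rng.normal(size=(9, 4))
        D = pairwise_diameters(x)
        for i in range(1, 10):
            for j in range(i, 10):
                assert D[i, j] == pytest.approx(class_diameter(x, i, j), abs=1e-9)


class TestOptimalSegmentation:
    def test_perfectly_separated_two_classes(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        result = optimal_segmentation(x, k_max=3)
        assert result.boundaries[2] == (1, 4)
        assert result.bstar[6, 2] == pytest.approx(0.0, abs=1e-12)
        # the drop from 1 to 2 classes equals the full diameter D(1, 6)
        assert result.fk[2] == pytest.approx(class_diameter(x, 1, 6))
        assert class_diameter(x, 1, 6) == pytest.approx(150.0)

    def test_k_equals_n_gives_zero_and_singletons(self, rng):
        x = rng.normal(size=(7, 2))
        result = optimal_segmentation(x, k_max=7)
        assert result.bstar[7, 7] == pytest.approx(0.0, abs=1e-12)
        assert result.boundaries[7] == tuple(range(1, 8))

    def test_bstar_monotone_nonincreasing(self, rng):
        x = rng.normal(size=(10, 3))
        result = optimal_segmentation(x, k_max=10)
        row = result.bstar_row
        assert np.all(np.diff(row) <= 1e-12)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 13))
            x = rng.normal(size=(n, int(rng.integers(1, 4))))
            k_max = min(5, n)
            result = optimal_segmentation(x, k_max=k_max)
            for k in range(2, k_max + 1):
                obj, cuts = brute_force_segmentation(x, k)
                assert result.bstar[n, k] == pytest.approx(obj, abs=1e-9)
                assert result.boundaries[k] == cuts

    def test_shift_invariance(self, rng):
        x = rng.normal(size=(8, 3))
        shifted = x + np.array([5.0, -2.0, 11.0])
        a = optimal_segmentation(x, k_max=4)
        b = optimal_segmentation(shifted, k_max=4)
        np.testing.assert_allclose(a.bstar_row, b.bstar_row, atol=1e-9)
        assert a.boundaries == b.boundaries

    def test_scale_invariance_through_nondimensionalization(self, rng):
        from ripart.preprocess import OrderedSampleMatrix, nondimensionalize

        values = np.abs(rng.normal(size=(9, 4))) + 0.5
        base = nondimensionalize(
            OrderedSampleMatrix(row_labels=tuple(range(1, 10)), values=values,
                                mode="summary")
        )
        scaled = nondimensionalize(
            OrderedSampleMatrix(row_labels=tuple(range(1, 10)),
                                values=values * [3.0, 0.2, 40.0, 7.0],
                                mode="summary")
        )
        a = optimal_segmentation(base, k_max=4)
        b = optimal_segmentation(scaled, k_max=4)
        assert a.boundaries == b.boundaries
        np.testing.assert_allclose(a.bstar_row, b.bstar_row, atol=1e-9)

    def test_decomposition_bound(self, rng):
        # any contiguous partition's diameter sum is >= B*, equal at the optimum
        x = rng.normal(size=(9, 2))
        result = optimal_segmentation(x, k_max=4)
        for k in (2, 3, 4):
            cuts = (1, *sorted(rng.choice(np.arange(2, 10), size=k - 1, replace=False)))
            ends = [*(c - 1 for c in cuts[1:]), 9]
            total = sum(class_diameter(x, s, e) for s, e in zip(cuts, ends))
            assert total >= result.bstar[9, k] - 1e-9
            opt_total = sum(
                class_diameter(x, s, e) for s, e in result.classes_at(k)
            )
            assert opt_total == pytest.approx(result.bstar[9, k], abs=1e-9)

    def test_domain_errors(self, rng):
        with pytest.raises(ValueError):
            optimal_segmentation(rng.normal(size=(4, 2)), k_max=5)
        with pytest.raises(ValueError):
            brute_force_segmentation(rng.normal(size=(4, 2)), 5)

    def test_bruteforce_budget_refused(self):
        with pytest.raises(ValueError, match="refusing"):
            brute_force_segmentation(np.zeros((200, 1)), 10)


class TestSlopeAndSelection:
    def test_slope_is_successive_drop(self):
        f = slope_curve([10.0, 2.0, 1.9, 1.85])
        np.testing.assert_allclose(f, [8.0, 0.1, 0.05])

    def test_constant_bstar_gives_zero_slopes(self):
        assert slope_curve([4.0, 4.0, 4.0]).tolist() == [0.0, 0.0]

    def test_increasing_bstar_rejected(self):
        with pytest.raises(ValueError):
            slope_curve([1.0, 5.0])

    @pytest.mark.parametrize("rule", ["elbow", "argmax"])
    def test_dominant_first_drop_selects_two(self, rule):
        # both rules agree when only the first drop is substantial
        assert select_k([8.0, 0.1, 0.05], b_total=10.0, rule=rule) == 2

    def test_sustained_drops_extend_the_elbow(self):
        # two substantial drops then noise: elbow continues to 3, argmax stops at 2
        f = [6.0, 3.0, 0.05, 0.02]
        assert select_k(f, b_total=10.0, rule="elbow") == 3
        assert select_k(f, b_total=10.0, rule="argmax") == 2

    @pytest.mark.parametrize("rule", ["elbow", "argmax"])
    def test_no_substantial_drop_means_no_partition(self, rule):
        assert select_k([0.01, 0.02, 0.001], b_total=10.0, rule=rule) == 1

    def test_three_phase_recovery_on_well_separated_data(self, rng):
        # between-segment shift 5x the within-segment SD: k_opt = 3 and the
        # true boundaries are recovered in (at least) 19 of 20 replicates
        hits = 0
        for _ in range(20):
            x = np.concatenate([
                rng.normal(0.0, 1.0, 6),
                rng.normal(5.0, 1.0, 6),
                rng.normal(10.0, 1.0, 5),
            ])
            result = optimal_segmentation(x, k_max=6)
            if result.k_opt == 3 and result.boundaries[3] == (1, 7, 13):
                hits += 1
        assert hits >= 19
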
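"""Cleaning, normality, Box-Cox, percentile profiles and ordered matrices."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripart.preprocess import (
    InsufficientSampleError,
    PercentileGrid,
    boxcox_transform,
    build_matrix,
    dixon_outlier_removal,
    ks_normality,
    nondimensionalize,
    percentile_profile,
)
from ripart.screening import SubjectRecord

from conftest import flat_spec
from ripart.synthetic import generate_cohort


class TestDixon:
    def test_extreme_value_removed(self):
        result = dixon_outlier_removal([1, 2, 3, 4, 100])
        assert result.kept.tolist() == [1, 2, 3, 4]
        assert result.removed.tolist() == [100]

    def test_clean_sample_untouched(self):
        result = dixon_outlier_removal([1, 2, 3, 4, 5])
        assert result.kept.tolist() == [1, 2, 3, 4, 5]
        assert result.removed.size == 0

    def test_constant_sample_no_outlier(self):
        result = dixon_outlier_removal([7.0] * 6)
        assert result.kept.tolist() == [7.0] * 6
        assert result.removed.size == 0

    def test_iterates_until_stable(self):
        # removing 1000 exposes 100 as the next extreme
        result = dixon_outlier_removal([1, 2, 3, 4, 100, 1000])
        assert set(result.removed.tolist()) == {100.0, 1000.0}
        assert result.kept.tolist() == [1, 2, 3, 4]

    def test_low_end_removed_too(self):
        result = dixon_outlier_removal([-100, 10, 11, 12, 13])
        assert result.removed.tolist() == [-100.0]

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            dixon_outlier_removal([1.0, 2.0])

    def test_heavy_removal_warns(self):
        with pytest.warns(UserWarning, match="Dixon"):
            dixon_outlier_removal([1, 2, 3, 4, 100, 1000], max_fraction=0.05)

    def test_survivors_outside_tukey_fences_flagged_not_removed(self, rng):
        values = np.concatenate([rng.normal(10, 1, 200), [16.0]])
        result = dixon_outlier_removal(values)
        # 16 is ~6 SD out but the Dixon gap ratio does not fire on it
        if 16.0 in result.kept:
            assert 16.0 in result.flagged


class TestNormalityAndBoxCox:
    def test_gaussian_sample_passes(self, rng):
        assert ks_normality(rng.normal(0, 1, 10_000)).is_gaussian

    def test_lognormal_sample_fails(self, rng):
        assert not ks_normality(rng.lognormal(0, 0.6, 10_000)).is_gaussian

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            ks_normality([1.0, 2.0, 3.0, 4.0])

    def test_constant_sample_degenerate(self):
        result = ks_normality([5.0] * 10)
        assert result.degenerate and not result.is_gaussian

    def test_lambda_near_one_for_normal_data(self, rng):
        values = rng.normal(50, 5, 10_000)
        _, lam = boxcox_transform(values)
        assert abs(lam - 1.0) < 0.15

    def test_lambda_near_zero_for_lognormal_data(self, rng):
        values = rng.lognormal(3.0, 0.5, 10_000)
        _, lam = boxcox_transform(values)
        assert abs(lam) < 0.15

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_transform([1.0, 0.0, 2.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.01, 1e4), min_size=5, max_size=40, unique=True))
    def test_rank_order_preserved(self, values):
        arr = np.asarray(values)
        out, _ = boxcox_transform(arr)
        assert np.array_equal(np.argsort(out), np.argsort(arr))


class TestPercentileProfile:
    def test_maximum_is_p100(self):
        profile = percentile_profile(np.arange(1, 101))
        assert profile[-1] == 100.0

    def test_constant_sample_all_entries_equal(self):
        profile = percentile_profile([3.5] * 25)
        assert profile.tolist() == [3.5] * 20

    def test_median_by_rank_interpolation(self):
        profile = percentile_profile(np.arange(1, 100))  # n = 99
        grid = PercentileGrid()
        p50_index = grid.probabilities.index(0.5)
        assert profile[p50_index] == pytest.approx(50.0)  # rank 0.5 * 100

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            percentile_profile(np.arange(19))

    def test_profile_monotone_nondecreasing(self, rng):
        profile = percentile_profile(rng.lognormal(1, 0.7, 500))
        assert np.all(np.diff(profile) >= 0)

    def test_invariant_under_monotone_transform_at_exact_ranks(self, rng):
        # n = 39 puts every grid rank p*(n+1) on an integer, so the profile
        # commutes exactly with a strictly increasing transform
        values = rng.normal(10, 2, 39)
        direct = percentile_profile(values)
        via_exp = np.log(percentile_profile(np.exp(values)))
        np.testing.assert_allclose(via_exp, direct, rtol=1e-12)


def _records_for_matrix(n_per_age_sex=30, seed=0):
    return generate_cohort(flat_spec(n_per_age_sex=n_per_age_sex), seed=seed)


class TestMatrix:
    def test_percentile_mode_shape(self):
        matrix = build_matrix(_records_for_matrix(), "CK", "percentile")
        assert matrix.values.shape == (17, 20)
        assert matrix.row_labels == tuple(range(1, 18))

    def test_summary_mode_shape(self, panel_cohort):
        matrix = build_matrix(panel_cohort, ["AST", "LDH", "CK", "CKMB"], "summary")
        assert matrix.values.shape == (17, 4)
        assert matrix.feature_labels == ("AST", "LDH", "CK", "CKMB")

    def test_missing_age_bin_named(self):
        records = [r for r in _records_for_matrix() if r.age_years != 9]
        with pytest.raises(ValueError, match="age bin 9 absent"):
            build_matrix(records, "CK", "percentile")

    def test_rows_are_profiles_of_bins(self):
        records = _records_for_matrix()
        matrix = build_matrix(records, "CK", "percentile")
        bin_5 = [r.analytes["CK"] for r in records if r.age_years == 5]
        np.testing.assert_allclose(matrix.values[4], percentile_profile(bin_5))


class TestNondimensionalize:
    def test_direct_division(self):
        from ripart.preprocess import OrderedSampleMatrix

        matrix = OrderedSampleMatrix(
            row_labels=(1, 2), values=np.array([[2.0, 10.0], [4.0, 5.0]]),
            mode="summary",
        )
        result = nondimensionalize(matrix)
        np.testing.assert_allclose(result.normalized, [[0.5, 1.0], [1.0, 0.5]])
        assert result.normalized.max(axis=0).tolist() == [1.0, 1.0]

    def test_idempotent_and_scale_invariant(self):
        from ripart.preprocess import OrderedSampleMatrix

        values = np.array([[2.0, 10.0], [4.0, 5.0]])
        base = nondimensionalize(
            OrderedSampleMatrix(row_labels=(1, 2), values=values, mode="summary")
        )
        rescaled = nondimensionalize(
            OrderedSampleMatrix(row_labels=(1, 2), values=values * [1000.0, 0.01],
                                mode="summary")
        )
        np.testing.assert_allclose(rescaled.normalized, base.normalized)
        twice = nondimensionalize(
            OrderedSampleMatrix(row_labels=(1, 2), values=base.normalized,
                                mode="summary")
        )
        np.testing.assert_allclose(twice.normalized, base.normalized)

    def test_zero_column_rejected(self):
        from ripart.preprocess import OrderedSampleMatrix

        matrix = OrderedSampleMatrix(
            row_labels=(1, 2), values=np.array([[0.0, 1.0], [0.0, 2.0]]),
            mode="summary",
        )
        with pytest.raises(ValueError, match="column 0"):
            nondimensionalize(matrix)
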
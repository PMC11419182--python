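"""MMD statistic: oracle equivalence, permutation calibration, learned features."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cohortshift as cs
from cohortshift.mmd import linear_kernel, rbf_kernel
from tests.conftest import shifted_gaussians


def naive_mmd2(Xp, Xq, kernel):
    """Literal double-loop evaluation of the unbiased U-statistic."""
    n = len(Xp)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total += (
                kernel(Xp[i : i + 1], Xp[j : j + 1])[0, 0]
                + kernel(Xq[i : i + 1], Xq[j : j + 1])[0, 0]
                - kernel(Xp[i : i + 1], Xq[j : j + 1])[0, 0]
                - kernel(Xp[j : j + 1], Xq[i : i + 1])[0, 0]
            )
    return total / (n * n - n)


class TestMMD2Unbiased:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n = int(rng.integers(2, 21))
            d = int(rng.integers(1, 11))
            Xp = rng.standard_normal((n, d))
            Xq = rng.standard_normal((n, d)) + rng.normal(scale=0.5)
            kernel = linear_kernel if trial % 2 == 0 else rbf_kernel(1.3)
            assert abs(cs.mmd2_unbiased(Xp, Xq, kernel) - naive_mmd2(Xp, Xq, kernel)) < 1e-10

    def test_identical_inputs_give_exact_zero(self):
        X = np.random.default_rng(1).standard_normal((10, 3))
        assert cs.mmd2_unbiased(X, X) == 0.0

    def test_one_dimensional_linear_kernel_hand_example(self):
        # D_p = {0, 2}, D_q = {1, 3}: MMD^2_u = (mean_p - mean_q)^2 = 1
        assert cs.mmd2_unbiased([[0.0], [2.0]], [[1.0], [3.0]]) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(2)
        Xp, Xq = shifted_gaussians(15, 4, 0.7, 3)
        assert cs.mmd2_unbiased(Xp, Xq) == pytest.approx(cs.mmd2_unbiased(Xq, Xp), abs=1e-12)

    def test_unbiased_under_the_null(self):
        # U-statistic: mean over replicates within Monte-Carlo error of 0
        rng = np.random.default_rng(4)
        vals = [
            cs.mmd2_unbiased(rng.standard_normal((10, 2)), rng.standard_normal((10, 2)))
            for _ in range(1500)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * se

    def test_errors(self):
        with pytest.raises(ValueError):
            cs.mmd2_unbiased([[1.0]], [[2.0]])  # n < 2
        with pytest.raises(ValueError):
            cs.mmd2_unbiased([[1.0, 2.0]] * 3, [[1.0]] * 3)  # dim mismatch

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.0, 2.0))
    def test_expected_value_tracks_linear_kernel_closed_form(self, seed, shift):
        # E[MMD^2_u] = ||mu_p - mu_q||^2 under the linear kernel
        rng = np.random.default_rng(seed)
        vals = [
            cs.mmd2_unbiased(
                rng.standard_normal((40, 3)), rng.standard_normal((40, 3)) + shift / np.sqrt(3)
            )
            for _ in range(40)
        ]
        assert np.mean(vals) == pytest.approx(shift**2, abs=0.6 + 0.3 * shift)


class TestPermutationTest:
    def test_minimal_p_when_observed_exceeds_all_permutations(self):
        Xp, Xq = shifted_gaussians(30, 3, 8.0, 0)  # huge shift
        _, p = cs.permutation_test(Xp, Xq, B=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_p_is_one_for_degenerate_identical_samples(self):
        X = np.ones((5, 2))
        _, p = cs.permutation_test(X, X.copy(), B=19, seed=0)
        assert p == 1.0

    def test_statistic_matches_direct_estimator(self):
        Xp, Xq = shifted_gaussians(20, 4, 0.5, 5)
        stat, _ = cs.permutation_test(Xp, Xq, B=5, seed=2)
        assert stat == pytest.approx(cs.mmd2_unbiased(Xp, Xq), abs=1e-10)

    def test_requires_at_least_one_permutation(self):
        Xp, Xq = shifted_gaussians(5, 2, 0.0, 0)
        with pytest.raises(ValueError):
            cs.permutation_test(Xp, Xq, B=0)


class TestFeatureMap:
    def _train(self, X, labels, seed=0, epochs=60):
        return cs.train_feature_map(X, labels, hidden=(16, 16, 8), epochs=epochs, seed=seed)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 5))
        lab = {"grp": np.where(X[:, 0] > 0, "a", "b")}
        fm1 = self._train(X, lab, seed=3, epochs=20)
        fm2 = self._train(X, lab, seed=3, epochs=20)
        np.testing.assert_array_equal(fm1.features(X), fm2.features(X))

    def test_separable_groups_learned_and_shift_detected(self):
        rng = np.random.default_rng(1)
        Xa = rng.standard_normal((80, 4)) + np.r_[4.0, 0, 0, 0]
        Xb = rng.standard_normal((80, 4)) - np.r_[4.0, 0, 0, 0]
        X = np.vstack([Xa, Xb])
        lab = np.array(["a"] * 80 + ["b"] * 80)
        fm = self._train(X, {"grp": lab}, epochs=150)
        assert fm.network.head_accuracy(X, "grp", (lab == "b").astype(int)) > 0.95
        assert cs.mmd2_unbiased(fm.features(Xa), fm.features(Xb)) > 0.0

    def test_single_group_attribute_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        labels = {"only": np.array(["x"] * 40), "two": np.where(X[:, 0] > 0, "a", "b")}
        with pytest.warns(UserWarning, match="single group"):
            fm = self._train(X, labels, epochs=5)
        assert fm.skipped_attributes == ["only"]
        assert fm.attributes == ["two"]

    def test_nonfinite_and_all_missing_inputs_error(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="missing"):
            cs.train_feature_map(X, {"a": np.full(10, np.nan)})
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            cs.train_feature_map(X, {"a": np.array(["x", "y"] * 5)})


class TestPairwiseShift:
    def _three_group_report(self, B=99, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.standard_normal((60, 4)),          # g1
                rng.standard_normal((60, 4)),          # g2: same distribution as g1
                rng.standard_normal((60, 4)) + 2.5,    # g3: shifted
            ]
        )
        groups = np.array(["g1"] * 60 + ["g2"] * 60 + ["g3"] * 60)
        fm = cs.train_feature_map(X, {"grp": groups}, hidden=(16, 16, 8), epochs=80, seed=seed)
        return cs.pairwise_shift(fm, X, groups, attribute="grp", B=B, seed=seed)

    def test_linkage_joins_the_identical_pair_first(self):
        rep = self._three_group_report()
        assert rep.mmd2[0, 1] < min(rep.mmd2[0, 2], rep.mmd2[1, 2])
        first_merge = sorted(rep.linkage_matrix[0, :2].astype(int))
        assert first_merge == [0, 1]  # g1 and g2

    def test_matrices_symmetric_zero_diagonal_valid_p(self):
        rep = self._three_group_report()
        np.testing.assert_array_equal(rep.mmd2, rep.mmd2.T)
        np.testing.assert_array_equal(np.diag(rep.mmd2), 0.0)
        off = rep.p_values[~np.eye(3, dtype=bool)]
        assert np.all(off >= 1 / (rep.B + 1)) and np.all(off <= 1.0)

    def test_json_round_trip_bit_identical(self):
        rep = self._three_group_report()
        back = cs.ShiftReport.from_json(rep.to_json())
        np.testing.assert_array_equal(back.mmd2, rep.mmd2)
        np.testing.assert_array_equal(back.p_values, rep.p_values)
        np.testing.assert_array_equal(back.linkage_matrix, rep.linkage_matrix)

    def test_tiny_group_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((41, 3))
        groups = np.array(["a"] * 20 + ["b"] * 20 + ["c"])
        fm = cs.train_feature_map(X, {"grp": groups}, hidden=(8, 8, 4), epochs=5, seed=0)
        with pytest.warns(UserWarning, match="dropped"):
            rep = cs.pairwise_shift(fm, X, groups, B=19, seed=0)
        assert rep.dropped_groups == ["c"]
        assert rep.groups == ["a", "b"]


def test_mmd_monotone_in_shift_magnitude():
    """Averaged MMD^2 estimates are non-decreasing over a shift grid."""
    rng = np.random.default_rng(6)
    means = []
    for shift in (0.0, 0.5, 1.0, 2.0):
        vals = [
            cs.mmd2_unbiased(rng.standard_normal((60, 3)), rng.standard_normal((60, 3)) + shift)
            for _ in range(60)
        ]
        means.append(np.mean(vals))
    assert all(means[i] <= means[i + 1] + 0.05 for i in range(3))
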
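"""Window means, normed differences, permutation tests and tau-b."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clozanc import (
    CohortValidationError,
    EmptyWindowError,
    group_summary,
    kendall_tau_b,
    normed_difference,
    permutation_test,
    window_means,
)


def _la_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "marker_id", "pos", "dos_afr", "dos_eas", "dos_eur"])


class TestWindowMean:
    def test_constant_field_returns_itself(self):
        la = _la_frame(
            [("A", f"M{i}", 1000 + 100 * i, 0.5, 0.5, 1.0) for i in range(5)]
        )
        means = window_means(la, center_pos=1200, halfwidth=1000)
        assert means.loc["A", ["dos_afr", "dos_eas", "dos_eur"]].tolist() == [0.5, 0.5, 1.0]

    def test_two_marker_midpoint(self):
        la = _la_frame([("A", "M1", 900, 0, 2, 0), ("A", "M2", 1100, 2, 0, 0)])
        means = window_means(la, center_pos=1000, halfwidth=1000)
        assert means.loc["A", ["dos_afr", "dos_eas", "dos_eur"]].tolist() == [1.0, 1.0, 0.0]

    def test_only_in_window_markers_enter_the_mean(self):
        positions = [500, 900, 1000, 1100, 2500]
        afr = [2.0, 1.0, 0.5, 0.0, 2.0]
        la = _la_frame(
            [("A", f"M{i}", p, a, 2.0 - a, 0.0) for i, (p, a) in enumerate(zip(positions, afr))]
        )
        means = window_means(la, center_pos=1000, halfwidth=150)  # closed window
        in_window = [1.0, 0.5, 0.0]  # markers at 900, 1000, 1100
        assert means.loc["A", "dos_afr"] == pytest.approx(sum(in_window) / 3)
        assert means.loc["A", "n_markers_in_window"] == 3

    def test_empty_window_error_names_bounds(self):
        la = _la_frame([("A", "M1", 10_000, 1, 1, 0)])
        with pytest.raises(EmptyWindowError, match=r"\[0, 2000\]"):
            window_means(la, center_pos=1000, halfwidth=1000)


class TestNormedDifference:
    def test_symmetric_inputs_cancel(self):
        assert normed_difference(0.7, 0.7) == 0.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.470, 0.641, -0.154), (0.213, 1.344, -0.726)],
    )
    def test_three_decimal_reference_values(self, a, b, expected):
        assert round(normed_difference(a, b), 3) == expected

    def test_undefined_for_zero_total(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(normed_difference(0.0, 0.0))

    def test_negative_dosages_rejected(self):
        with pytest.raises(CohortValidationError):
            normed_difference(-0.1, 0.5)

    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0))
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        d = normed_difference(a, b)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-normed_difference(b, a), abs=1e-12)


class TestGroupSummary:
    @staticmethod
    def _windows(values):
        ids = [f"S{i}" for i in range(len(values))]
        return pd.DataFrame(values, index=pd.Index(ids, name="subject_id"),
                            columns=["dos_afr", "dos_eas", "dos_eur"])

    def test_identical_groups_have_zero_differences(self):
        windows = self._windows([(0.4, 0.6, 1.0)] * 6)
        labels = pd.Series(["x", "y"] * 3, index=windows.index)
        assert (group_summary(windows, labels)["difference"].abs() < 1e-12).all()

    def test_two_subject_groups_match_hand_computation(self):
        windows = self._windows([(0.2, 0.8, 1.0), (0.6, 0.4, 1.0)])
        labels = pd.Series(["g1", "g2"], index=windows.index)
        summary = group_summary(windows, labels)
        assert summary.loc["AFR", "difference"] == pytest.approx(0.2 - 0.6)
        # per-subject normed differences: (0.2-0.8)/1.0 vs (0.6-0.4)/1.0
        assert summary.loc["AFR-EAS", "difference"] == pytest.approx(-0.6 - 0.2)

    def test_difference_changes_sign_with_label_swap(self):
        rng = np.random.default_rng(0)
        windows = self._windows(rng.dirichlet((1, 1, 1), 10) * 2)
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=windows.index)
        swapped = labels.map({"a": "b", "b": "a"})
        s1 = group_summary(windows, labels)["difference"]
        s2 = group_summary(windows, swapped)["difference"]
        assert np.allclose(s1.to_numpy(), -s2.to_numpy())


def exhaustive_permutation_p(values, labels):
    """Enumerate every relabeling preserving group sizes (oracle)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    idx1 = np.flatnonzero(labels == groups[0])
    n1 = len(idx1)
    observed = values[idx1].mean() - values[np.flatnonzero(labels != groups[0])].mean()
    total = values.sum()
    n = len(values)
    count = exceed = 0
    for subset in combinations(range(n), n1):
        s = values[list(subset)].sum()
        stat = s / n1 - (total - s) / (n - n1)
        count += 1
        if abs(stat) >= abs(observed) - 1e-12:
            exceed += 1
    return exceed / count


class TestPermutationTest:
    def test_null_data_gives_large_p(self):
        values = np.array([1.0, 2.0, 3.0] * 4)
        labels = ["a", "b"] * 6
        result = permutation_test(values, labels, n_perm=2000, seed=0)
        assert result.p_point >= 0.5

    def test_matches_exhaustive_enumeration_at_n6(self):
        values = np.array([1.3, 0.2, 2.1, 0.9, 1.7, 0.4])
        labels = ["a", "a", "a", "b", "b", "b"]
        exact = exhaustive_permutation_p(values, labels)
        result = permutation_test(values, labels, n_perm=10_000, seed=1)
        assert abs(result.p_point - exact) <= 0.02

    def test_monte_carlo_converges_to_exhaustive_at_n10(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=10)
        labels = ["a"] * 5 + ["b"] * 5
        exact = exhaustive_permutation_p(values, labels)
        result = permutation_test(values, labels, n_perm=20_000, seed=3)
        assert abs(result.p_point - exact) <= 0.02

    def test_separated_groups_report_below_resolution(self):
        values = np.array([0.0] * 15 + [5.0] * 15)
        labels = ["low"] * 15 + ["high"] * 15
        result = permutation_test(values, labels, n_perm=10_000, seed=4)
        assert result.n_exceed == 0
        assert result.p_report == "<1.00E-04"
        assert result.p_point == pytest.approx(1 / 10_001)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=20)
        labels = ["a"] * 10 + ["b"] * 10
        r1 = permutation_test(values, labels, n_perm=500, seed=42)
        r2 = permutation_test(values, labels, n_perm=500, seed=42)
        assert (r1.n_exceed, r1.p_point) == (r2.n_exceed, r2.p_point)

    def test_empty_group_rejected(self):
        with pytest.raises(CohortValidationError):
            permutation_test(np.ones(3), ["a", "a", "a"])


def tau_b_oracle(x, y):
    """O(n^2) concordant/discordant count with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    pairs_x = concordant + discordant + ties_y  # pairs not tied in x
    pairs_y = concordant + discordant + ties_x
    return (concordant - discordant) / np.sqrt(pairs_x * pairs_y)


class TestKendallTauB:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        tau, _ = kendall_tau_b(x, x)
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        tau, _ = kendall_tau_b(x, x[::-1])
        assert tau == pytest.approx(-1.0)

    def test_tie_correction_matches_quadratic_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([0.5, 0.1, 0.9, 0.4, 0.8])
        tau, p = kendall_tau_b(x, y)
        assert tau == pytest.approx(tau_b_oracle(x, y), abs=1e-12)
        assert 0 < p <= 1

    def test_constant_input_reported_missing(self):
        with pytest.warns(RuntimeWarning):
            tau, p = kendall_tau_b(np.ones(5), np.arange(5.0))
        assert np.isnan(tau) and np.isnan(p)
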
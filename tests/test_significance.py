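"""Contingency tables, chi-squared p-values, threshold scans and the
multiplicity corrections."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from s5m.data import ShapeletCandidate
from s5m.significance import (ContingencyTable, bonferroni_threshold,
                              chi2_pvalue, contingency_table, min_pvalue,
                              min_pvalues, tarone_threshold)
from tests.conftest import make_dataset


def cand(*values):
    return ShapeletCandidate(values=np.array(values, dtype=float))


class TestContingencyTable:
    def test_everything_predicted_positive(self):
        ds = make_dataset([[0, 0]] * 5, [1, 1, 1, 0, 0])
        t = contingency_table(cand(0, 0), theta=0.0, dataset=ds)
        assert (t.a, t.b, t.c, t.d) == (3, 2, 0, 0)

    def test_nothing_predicted_positive(self):
        ds = make_dataset([[9, 9], [9, 9], [8, 8]], [1, 0, 0])
        t = contingency_table(cand(0, 0), theta=0.5, dataset=ds)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 1, 2)

    def test_clean_split(self):
        # distances of (0,0) to the four series: 0.1*sqrt2? use explicit constants
        ds = make_dataset([[0.1, 0], [0.2, 0], [0.9, 0], [1.0, 0]], [1, 1, 0, 0])
        t = contingency_table(cand(0, 0), theta=0.5, dataset=ds)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)

    def test_single_class_dataset_rejected(self):
        ds = make_dataset([[0, 0], [1, 1]], [1, 1])
        with pytest.raises(ValueError):
            contingency_table(cand(0, 0), 1.0, ds)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 1, 1)


class TestChi2:
    def test_perfect_independence(self):
        assert chi2_pvalue(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_perfect_association_matches_hand_formula(self):
        # stat = n (ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 20
        p = chi2_pvalue(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_degenerate_prediction_margin(self):
        assert chi2_pvalue(ContingencyTable(0, 0, 3, 3)) == 1.0
        assert chi2_pvalue(ContingencyTable(3, 3, 0, 0)) == 1.0

    @pytest.mark.parametrize("yates", [False, True])
    def test_matches_scipy_either_correction(self, rng, yates):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 30, size=4)
            ours = chi2_pvalue(ContingencyTable(a, b, c, d), yates=yates)
            _, expected, _, _ = chi2_contingency([[a, b], [c, d]], correction=yates)
            assert ours == pytest.approx(expected, rel=1e-10)

    def test_label_relabeling_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, size=4) + 1
            p1 = chi2_pvalue(ContingencyTable(a, b, c, d))
            p2 = chi2_pvalue(ContingencyTable(d, c, b, a))  # swap rows and columns
            assert p1 == pytest.approx(p2, rel=1e-12)


def brute_force_min_pvalue(distances, labels):
    """Oracle: double loop over (threshold, table)."""
    best_p, best_theta = 2.0, None
    for theta in sorted(set(distances)):
        pred = [d <= theta for d in distances]
        a = sum(p and l for p, l in zip(pred, labels))
        b = sum(p and not l for p, l in zip(pred, labels))
        c = sum((not p) and l for p, l in zip(pred, labels))
        d = sum((not p) and (not l) for p, l in zip(pred, labels))
        p_val = chi2_pvalue(ContingencyTable(a, b, c, d))
        if p_val < best_p - 1e-15:
            best_p, best_theta = p_val, theta
    return min(best_p, 1.0), best_theta


class TestMinPvalue:
    def test_perfectly_separating_shapelet(self):
        # all case distances below all control distances, n=10 balanced
        dists = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 1.1, 1.2, 1.3, 1.4, 1.5])
        labels = np.array([1] * 5 + [0] * 5)
        p, theta = min_pvalues(dists[None, :], labels)
        expected = chi2_pvalue(ContingencyTable(5, 0, 0, 5))
        assert p[0] == pytest.approx(expected, rel=1e-12)
        assert theta[0] == pytest.approx(0.5)

    def test_identical_distances_are_degenerate(self):
        p, _ = min_pvalues(np.full((1, 6), 2.0), np.array([1, 1, 1, 0, 0, 0]))
        assert p[0] == 1.0

    def test_toy_four_series(self):
        dists = np.array([[0.1, 0.2, 0.9, 1.0]])
        labels = np.array([1, 1, 0, 0])
        p, theta = min_pvalues(dists, labels)
        assert p[0] == pytest.approx(chi2_pvalue(ContingencyTable(2, 0, 0, 2)), rel=1e-12)
        assert theta[0] == pytest.approx(0.2)

    def test_matches_brute_force_oracle_on_random_data(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 15))
            labels = np.zeros(n, dtype=int)
            labels[: n // 2] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # duplicate-heavy distances to exercise threshold collapsing
            dists = rng.integers(0, 5, size=n).astype(float) / 2.0
            p, theta = min_pvalues(dists[None, :], labels)
            p_exp, theta_exp = brute_force_min_pvalue(dists.tolist(), labels.tolist())
            assert p[0] == pytest.approx(p_exp, rel=1e-9)
            if p_exp < 1.0:
                assert theta[0] == pytest.approx(theta_exp)

    def test_min_pvalue_wrapper(self, toy_dataset):
        scored = min_pvalue(cand(1, 2, 3), toy_dataset)
        dists = scored.distances
        p_exp, theta_exp = brute_force_min_pvalue(dists.tolist(),
                                                  toy_dataset.labels.tolist())
        assert scored.p_min == pytest.approx(p_exp, rel=1e-9)
        assert scored.best_theta == pytest.approx(theta_exp)

    def test_ties_break_to_smallest_theta(self):
        # symmetric distances: splitting low or high gives the same p
        dists = np.array([[1.0, 2.0, 3.0, 4.0]])
        labels = np.array([1, 1, 0, 0])
        _, theta = min_pvalues(dists, labels)
        assert theta[0] == 2.0


class TestCorrections:
    @pytest.mark.parametrize("alpha, n_cand, n, expected", [
        (0.05, 10, 5, 0.001), (0.05, 1, 1, 0.05), (0.01, 100, 10, 1e-5),
    ])
    def test_bonferroni(self, alpha, n_cand, n, expected):
        assert bonferroni_threshold(alpha, n_cand, n) == pytest.approx(expected)

    def test_bonferroni_rejects_zero_candidates(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0, 10)

    def test_tarone_fixed_point_example(self):
        # enumerate k: alpha/3 is the largest delta with at most k testable
        delta, testable = tarone_threshold([0.001, 0.002, 0.01, 0.04, 0.2], 0.05)
        assert delta == pytest.approx(0.05 / 3)
        assert testable.sum() == 3

    def test_tarone_nothing_testable(self):
        delta, testable = tarone_threshold([1.0] * 5, 0.05)
        assert delta == 0.05
        assert testable.sum() == 0

    def test_tarone_single_tiny_p(self):
        delta, testable = tarone_threshold([1e-6], 0.05)
        assert delta == 0.05
        assert testable.sum() == 1

    def test_tarone_never_below_bonferroni_and_fwer_budget(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 60))
            p = rng.uniform(0, 1, size=m) ** rng.uniform(0.3, 3)
            alpha = float(rng.uniform(0.01, 0.2))
            delta, testable = tarone_threshold(p, alpha)
            assert delta >= bonferroni_threshold(alpha, m, 1) - 1e-15
            assert delta * testable.sum() <= alpha + 1e-12
            # delta is the largest feasible alpha/k
            k = round(alpha / delta)
            if k > 1:
                assert np.sum(p < alpha / (k - 1)) > k - 1
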
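"""End-to-end mining pipelines: the interleaved loop, its invariants, the
early-exit equivalence and the two-stage variants."""

import numpy as np
import pytest

from s5m.data import LabeledSeries, SeriesDataset
from s5m.mining import (PIPELINES, bonferroni_submodular,
                        feature_selection_tarone, run_pipeline, s5m_mine,
                        s5m_threshold, tarone_submodular)
from s5m.significance import chi2_pvalue, ContingencyTable
from tests.conftest import make_dataset


def planted_dataset(n_cases=20, n_controls=20, seed=0, sigma=0.3):
    """One strong planted pattern in every case; controls are flat noise."""
    rng = np.random.default_rng(seed)
    pattern = np.array([4.0, -4.0, 4.0, -4.0, 4.0])
    series = []
    for i in range(n_cases):
        background = rng.uniform(-sigma, sigma, size=12)
        off = int(rng.integers(12 - 5 + 1))
        background[off: off + 5] = pattern + rng.uniform(-sigma, sigma, size=5)
        series.append(LabeledSeries(values=background, label=1, id=f"case-{i}"))
    for i in range(n_controls):
        series.append(LabeledSeries(values=rng.uniform(-sigma, sigma, size=12),
                                    label=0, id=f"control-{i}"))
    return SeriesDataset(series=tuple(series)), pattern


class TestS5MMine:
    def test_planted_shapelet_found(self):
        ds, pattern = planted_dataset()
        result = s5m_mine(ds, alpha=0.05, window_lengths=[5], seed=1)
        assert result.n_significant >= 1
        top = result.significant[0]
        # the top shapelet separates the classes perfectly
        expected = chi2_pvalue(ContingencyTable(20, 0, 0, 20))
        assert top.p_min == pytest.approx(expected, rel=1e-9)
        assert result.delta > top.p_min

    def test_all_significant_below_delta_and_fwer_budget(self):
        ds, _ = planted_dataset(seed=3)
        result = s5m_mine(ds, alpha=0.05, window_lengths=[4, 5], seed=0)
        for s in result.significant:
            assert s.p_min < result.delta
        assert result.delta * result.n_significant <= result.alpha + 1e-12
        assert result.delta <= result.alpha

    def test_accounting_partition(self):
        ds, _ = planted_dataset(seed=4)
        result = s5m_mine(ds, alpha=0.05, window_lengths=[5], seed=0)
        processed = (result.n_significant + result.n_nonrepresentative
                     + result.n_evicted + result.n_pruned_early)
        assert processed == result.candidate_count

    def test_reproducible_given_seed(self):
        ds, _ = planted_dataset(seed=5)
        r1 = s5m_mine(ds, window_lengths=[5], seed=9)
        r2 = s5m_mine(ds, window_lengths=[5], seed=9)
        assert [tuple(s.candidate.values) for s in r1.significant] == \
               [tuple(s.candidate.values) for s in r2.significant]
        assert r1.delta == r2.delta

    def test_early_exit_equivalent_to_full_stream(self):
        for seed in range(5):
            ds, _ = planted_dataset(n_cases=8, n_controls=8, seed=seed, sigma=0.8)
            fast = s5m_mine(ds, window_lengths=[4], seed=seed, early_exit=True)
            full = s5m_mine(ds, window_lengths=[4], seed=seed, early_exit=False)
            assert [tuple(s.candidate.values) for s in fast.significant] == \
                   [tuple(s.candidate.values) for s in full.significant]
            assert fast.delta == full.delta

    def test_no_testable_candidate_returns_empty_with_alpha_floor(self, rng):
        # shuffled labels on identical series: every split is degenerate
        ds = make_dataset([[1, 2, 3, 4]] * 6, [1, 0, 1, 0, 1, 0])
        result = s5m_mine(ds, alpha=0.05, window_lengths=[3], seed=0)
        assert result.n_significant == 0
        assert result.delta == 0.05

    def test_duplicate_candidates_do_not_change_result(self):
        ds, _ = planted_dataset(n_cases=6, n_controls=6, seed=7)
        doubled = SeriesDataset(series=ds.series + ds.series)  # duplicates every window
        r1 = s5m_mine(ds, window_lengths=[5], seed=2)
        r2 = s5m_mine(doubled, window_lengths=[5], seed=2)
        # dedup collapses identical value sequences; the candidate pool is unchanged
        assert r2.candidate_count == r1.candidate_count

    def test_rejects_invalid_alpha(self, toy_dataset):
        with pytest.raises(ValueError):
            s5m_mine(toy_dataset, alpha=1.5, window_lengths=[2])


class TestComparisonPipelines:
    def test_tarone_submodular_subset_of_stage1(self):
        ds, _ = planted_dataset(seed=11)
        result = tarone_submodular(ds, window_lengths=[5], seed=0)
        for s in result.significant:
            assert s.p_min < result.delta

    def test_bonferroni_single_overwhelming_shapelet(self):
        ds, _ = planted_dataset(seed=12)
        result = bonferroni_submodular(ds, window_lengths=[5], seed=0)
        assert result.n_significant >= 1
        assert all(s.p_min < result.delta for s in result.significant)

    def test_bonferroni_redundant_survivors_collapse_to_representatives(self):
        # cases carry a near-identical pattern, so the Bonferroni survivors are
        # a cloud of mutually redundant windows; the representative stage must
        # not return near-duplicates
        from s5m.distance import similarity

        rng = np.random.default_rng(0)
        pattern = np.array([5.0, -5.0, 5.0])
        series = [LabeledSeries(values=pattern + rng.uniform(-0.01, 0.01, 3),
                                label=1, id=f"c{i}") for i in range(10)]
        series += [LabeledSeries(values=rng.uniform(-60, 60, 3), label=0, id=f"n{i}")
                   for i in range(10)]
        ds = SeriesDataset(series=tuple(series))
        result = bonferroni_submodular(ds, window_lengths=[3], seed=0)
        # while the discard set is empty both clipped gains can be zero, and
        # the 0.5 fallback coin-flips a few duplicates in; once it fills,
        # redundant arrivals are rejected outright, so the bulk of the cloud
        # must land outside the representative set
        assert 1 <= result.n_significant
        assert result.n_nonrepresentative >= result.n_significant
        values = result.shapelet_values()
        n_dupes = sum(similarity(values[i], values[j]) > 0.9
                      for i in range(len(values)) for j in range(i + 1, len(values)))
        assert n_dupes < len(values) ** 2 / 4

    def test_feature_selection_on_balanced_noise_is_empty(self):
        rng = np.random.default_rng(42)
        ds = make_dataset([rng.uniform(-1, 1, 10) for _ in range(20)],
                          [1, 0] * 10)
        result = feature_selection_tarone(ds, window_lengths=[4], seed=0)
        # label-blind representatives of pure noise are almost never testable
        assert result.n_significant <= 2

    def test_threshold_variant_tau_extremes(self):
        ds, _ = planted_dataset(n_cases=8, n_controls=8, seed=13)
        few = s5m_threshold(ds, window_lengths=[5], seed=0, tau=1e-9)
        assert few.n_significant <= 1  # everything after the first is "redundant"
        many = s5m_threshold(ds, window_lengths=[5], seed=0, tau=1 - 1e-12)
        assert many.n_significant >= few.n_significant

    def test_threshold_variant_draws_tau_from_run_seed(self):
        ds, _ = planted_dataset(n_cases=6, n_controls=6, seed=14)
        r1 = s5m_threshold(ds, window_lengths=[5], seed=5)
        r2 = s5m_threshold(ds, window_lengths=[5], seed=5)
        assert r1.threshold_tau == r2.threshold_tau
        assert 0.0 < r1.threshold_tau < 1.0

    def test_dispatch_and_unknown_method(self, toy_dataset):
        with pytest.raises(ValueError):
            run_pipeline("magic", toy_dataset, window_lengths=[2])
        assert set(PIPELINES) == {"s5m", "s5m_threshold", "feature_selection_tarone",
                                  "bonferroni_submodular", "tarone_submodular"}

    def test_single_candidate_dataset_all_pipelines_agree(self):
        # two series, one window each -> one candidate after dedup of noise
        ds = make_dataset([[5, -5, 5], [0.1, 0.0, -0.1]], [1, 0])
        results = {}
        for name in ("s5m", "tarone_submodular", "feature_selection_tarone"):
            results[name] = run_pipeline(name, ds, window_lengths=[3], seed=0)
        counts = {name: r.n_significant for name, r in results.items()}
        assert len(set(counts.values())) == 1
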
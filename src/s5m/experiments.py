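"""Reusable experiment drivers for the simulation study.

These functions regenerate the planted-shapelet benchmarks, run the mining
pipelines over a (sample size x noise) grid with repeated randomizations, and
score each run against the ground-truth prototypes.  The command-line
``compare`` subcommand, the acceptance checks and the test suite all share
this code so that reported numbers come from one implementation.
"""

from __future__ import annotations

import time
from typing import Sequence

import numpy as np

from .evaluation import evaluate_retrieval
from .mining import run_pipeline
from .optimizers import big_select, greedy_select
from .simulate import SimulationSpec, generate_labeled_dataset, generate_replicates
from .submodular import MixtureParams, pairwise_similarities

__all__ = [
    "run_method_comparison",
    "null_discovery_rate",
    "recovery_study",
    "optimizer_runtimes",
]


def _derive_seed(base: int, *parts: int) -> int:
    """Deterministic sub-seed below 2**31, distinct per grid cell."""
    h = int(base) & 0xFFFFFFFF
    for p in parts:
        h = (h * 1000003 + int(p) + 0x9E3779B9) % (2**31 - 1)
    return h


def run_method_comparison(methods: Sequence[str], n_grid: Sequence[int],
                          sigma_grid: Sequence[float], repetitions: int = 5,
                          alpha: float = 0.05, seed: int = 0,
                          series_length: int = 20) -> list[dict]:
    """Run every pipeline over the simulation grid and score retrievals.

    All methods in one grid cell see the identical dataset and share the run
    seed (common random numbers), so differences reflect the pipelines, not
    the draws.  Returns one row per (method, n, sigma, repetition).
    """
    rows: list[dict] = []
    for n in n_grid:
        for si, sigma in enumerate(sigma_grid):
            for rep in range(repetitions):
                run_seed = _derive_seed(seed, n, si, rep)
                spec = SimulationSpec(n_series=n, sigma=sigma,
                                      series_length=series_length, seed=run_seed)
                dataset, _ = generate_labeled_dataset(spec)
                truth = list(spec.prototypes)
                w = truth[0].size  # ground-truth width supplied to every method
                for method in methods:
                    t0 = time.perf_counter()
                    result = run_pipeline(method, dataset, alpha=alpha,
                                          window_lengths=[w], seed=run_seed)
                    report = evaluate_retrieval(result.shapelet_values(), truth)
                    rows.append({
                        "method": method, "n": n, "sigma": sigma, "repetition": rep,
                        "f1": report.f1, "precision": report.precision,
                        "recall": report.recall, "k_d": report.k_d,
                        "min_sim": report.min_sim,
                        "n_significant": result.n_significant,
                        "delta": result.delta,
                        "runtime": time.perf_counter() - t0,
                    })
    return rows


def null_discovery_rate(n_runs: int = 20, n_series: int = 100, sigma: float = 1.0,
                        series_length: int = 20, window_length: int = 7,
                        alpha: float = 0.05, seed: int = 0,
                        method: str = "s5m") -> tuple[float, list[int]]:
    """Fraction of pure-noise runs that yield at least one significant shapelet.

    Every series is uniform noise and labels are randomly shuffled, so any
    discovery is a false positive; the returned rate estimates the realized
    family-wise error rate of the pipeline.
    """
    from .data import LabeledSeries, SeriesDataset

    counts: list[int] = []
    for run in range(n_runs):
        rng = np.random.default_rng(_derive_seed(seed, 7919, run))
        labels = np.zeros(n_series, dtype=int)
        labels[: n_series // 2] = 1
        rng.shuffle(labels)
        series = tuple(
            LabeledSeries(values=rng.uniform(-sigma, sigma, size=series_length),
                          label=int(labels[i]), id=f"noise-{i}")
            for i in range(n_series)
        )
        dataset = SeriesDataset(series=series)
        result = run_pipeline(method, dataset, alpha=alpha,
                              window_lengths=[window_length],
                              seed=_derive_seed(seed, 104729, run))
        counts.append(result.n_significant)
    rate = float(np.mean([c > 0 for c in counts]))
    return rate, counts


def recovery_study(n_seeds: int = 5, n_series: int = 200, sigma: float = 0.5,
                   series_length: int = 20, alpha: float = 0.05,
                   seed: int = 0, method: str = "s5m") -> list[dict]:
    """Parameter recovery: retrieval scores per seed at a fixed (n, sigma)."""
    rows = []
    for rep in range(n_seeds):
        run_seed = _derive_seed(seed, 15485863, rep)
        spec = SimulationSpec(n_series=n_series, sigma=sigma,
                              series_length=series_length, seed=run_seed)
        dataset, _ = generate_labeled_dataset(spec)
        truth = list(spec.prototypes)
        result = run_pipeline(method, dataset, alpha=alpha,
                              window_lengths=[truth[0].size], seed=run_seed)
        report = evaluate_retrieval(result.shapelet_values(), truth)
        rows.append({"repetition": rep, "precision": report.precision,
                     "recall": report.recall, "f1": report.f1,
                     "n_significant": result.n_significant})
    return rows


def optimizer_runtimes(item_counts: Sequence[int] = (50, 100, 200, 400),
                       sigma: float = 1.0, seed: int = 0,
                       repeats: int = 3) -> dict[int, dict[str, float]]:
    """Wall time of greedy versus streaming selection on replicate sets.

    The greedy baseline re-evaluates the published objective from scratch at
    every step; the streaming optimizer maintains it incrementally.  Returns
    the best-of-``repeats`` time per item count and method.
    """
    params = MixtureParams()
    out: dict[int, dict[str, float]] = {}
    for count in item_counts:
        per_proto = max(count // 5, 1)
        items = generate_replicates(n_per_prototype=per_proto, sigma=sigma,
                                    seed=_derive_seed(seed, count))
        sim = pairwise_similarities(items)
        t_greedy = min(_timed(lambda: greedy_select(sim, params)) for _ in range(repeats))
        t_big = min(_timed(lambda: big_select(items, params,
                                              seed=_derive_seed(seed, count, 1)))
                    for _ in range(repeats))
        out[len(items)] = {"greedy": t_greedy, "big": t_big}
    return out


def _timed(fn) -> float:
    t0 = time.perf_counter()
    fn()
    return time.perf_counter() - t0
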
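"""Mining pipelines: the interleaved significance/representativeness loop and
the two-stage comparison strategies built from the same components.

The core pipeline (:func:`s5m_mine`) extracts sliding-window candidates,
scores each with its minimum chi-squared p-value over thresholds, and streams
candidates in ascending p-value order through the bidirectional iterative
greedy optimizer.  Candidates declared non-representative land in the discard
set and are *excluded from the multiple-testing correction*; representatives
count towards it.  After every addition the corrected threshold is tightened
to alpha / |R_hat| (never raised again), and representatives whose p-value no
longer clears it are evicted — largest p-value first, permanently.  Because
candidates arrive sorted and the threshold is monotone, the stream can stop at
the first candidate whose p-value already exceeds the threshold; the result is
identical to processing the full stream.

The comparison pipelines decouple the two concerns:

* ``feature_selection_tarone`` — representatives first (label-blind), then
  Tarone testing restricted to them;
* ``bonferroni_submodular``   — Bonferroni-significant candidates first, then
  representative selection among the survivors;
* ``tarone_submodular``       — Tarone-significant candidates first, then
  representative selection;
* ``s5m_threshold``           — the interleaved loop, but representativeness
  decided by the similarity-cutoff baseline with a cutoff drawn uniformly at
  random once per run.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data import SeriesDataset
from .distance import distance_profile, extract_candidates
from .significance import (ScoredShapelet, bonferroni_threshold, min_pvalues,
                           tarone_threshold)
from .submodular import MixtureParams, RepresentativeState
from .optimizers import big_step, _ratio_probability

__all__ = [
    "MiningResult",
    "s5m_mine",
    "feature_selection_tarone",
    "bonferroni_submodular",
    "tarone_submodular",
    "s5m_threshold",
    "run_pipeline",
    "PIPELINES",
]


@dataclass
class MiningResult:
    """Outcome of one mining run."""

    method: str
    significant: list[ScoredShapelet]
    delta: float
    alpha: float
    seed: int
    candidate_count: int
    n_nonrepresentative: int = 0
    n_evicted: int = 0
    n_pruned_early: int = 0
    threshold_tau: float | None = None
    params: MixtureParams = field(default_factory=MixtureParams)
    window_lengths: tuple[int, ...] = ()
    runtime_seconds: float = 0.0

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    @property
    def alpha_hat(self) -> float:
        return self.delta * self.n_significant

    def shapelet_values(self) -> list[np.ndarray]:
        return [s.candidate.values for s in self.significant]


def _score_all(dataset: SeriesDataset, window_lengths: Iterable[int], dedup: bool,
               znorm: bool = False):
    """Extract, score and ascending-p-sort the candidate pool."""
    dataset.require_both_classes()
    candidates = extract_candidates(dataset, window_lengths, dedup=dedup, znorm=znorm)
    dists = distance_profile(candidates, dataset)
    p_min, theta = min_pvalues(dists, dataset.labels)
    order = np.argsort(p_min, kind="stable")  # stable: ties keep extraction order
    return candidates, p_min, theta, order


def _scored(candidates, p_min, theta, idx: int) -> ScoredShapelet:
    return ScoredShapelet(candidate=candidates[idx], p_min=float(p_min[idx]),
                          best_theta=float(theta[idx]))


def _interleaved_mine(
    dataset: SeriesDataset,
    alpha: float,
    window_lengths: Iterable[int],
    params: MixtureParams,
    seed: int,
    dedup: bool,
    znorm: bool,
    early_exit: bool,
    method: str,
    tau: float | None,
) -> MiningResult:
    """Shared body of the interleaved pipelines (submodular or threshold rule)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    use_threshold_rule = method == "s5m_threshold"
    if use_threshold_rule and tau is None:
        tau = float(rng.uniform(0.0, 1.0))

    candidates, p_min, theta, order = _score_all(dataset, window_lengths, dedup, znorm)
    state = RepresentativeState(params)
    delta = alpha  # empty-R_hat convention: first candidate testable iff p < alpha
    rep_p: dict[int, float] = {}   # state index -> p_min
    cand_of: dict[int, int] = {}   # state index -> candidate index
    n_nonrep = 0
    n_evict = 0
    n_pruned = 0

    for pos, cand_idx in enumerate(order):
        p = float(p_min[cand_idx])
        if p >= delta and early_exit:
            n_pruned = len(order) - pos
            break
        if use_threshold_rule:
            idx = state.add_item(candidates[cand_idx].values)
            row = state.sim_matrix()[idx]
            accept = all(row[r] < tau for r in state.R_hat)
            state.assign(idx, to_representatives=accept)
        else:
            idx, accept = big_step(state, candidates[cand_idx].values, rng)
        if not accept:
            n_nonrep += 1
            continue
        cand_of[idx] = cand_idx
        rep_p[idx] = p
        # an already-untestable arrival is evicted before the threshold moves,
        # so processing the tail of the stream cannot change the result
        if p >= delta:
            state.demote(idx)
            del rep_p[idx]
            n_evict += 1
            continue
        delta = min(delta, alpha / len(state.R_hat))
        for victim in sorted(state.R_hat, key=lambda i: -rep_p[i]):
            if rep_p[victim] >= delta:
                state.demote(victim)
                del rep_p[victim]
                n_evict += 1

    significant = [_scored(candidates, p_min, theta, cand_of[i])
                   for i in sorted(state.R_hat, key=lambda i: p_min[cand_of[i]])]
    return MiningResult(
        method=method, significant=significant, delta=delta, alpha=alpha, seed=seed,
        candidate_count=len(candidates), n_nonrepresentative=n_nonrep,
        n_evicted=n_evict, n_pruned_early=n_pruned, threshold_tau=tau, params=params,
        window_lengths=tuple(sorted(set(int(w) for w in window_lengths))),
        runtime_seconds=time.perf_counter() - t0,
    )


def s5m_mine(dataset: SeriesDataset, alpha: float = 0.05,
             window_lengths: Iterable[int] = (), params: MixtureParams | None = None,
             seed: int = 0, dedup: bool = True, znorm: bool = False,
             early_exit: bool = True) -> MiningResult:
    """Interleaved mining: representativeness and significance decided together."""
    return _interleaved_mine(dataset, alpha, window_lengths, params or MixtureParams(),
                             seed, dedup, znorm, early_exit, "s5m", tau=None)


def s5m_threshold(dataset: SeriesDataset, alpha: float = 0.05,
                  window_lengths: Iterable[int] = (), params: MixtureParams | None = None,
                  seed: int = 0, dedup: bool = True, znorm: bool = False,
                  early_exit: bool = True, tau: float | None = None) -> MiningResult:
    """Interleaved loop with the similarity-cutoff representativeness rule.

    The cutoff tau is drawn uniformly on (0, 1) from the run's generator when
    not supplied.  As tau -> 1 every distinct candidate is representative and
    the loop degenerates to plain per-shapelet Tarone mining.
    """
    return _interleaved_mine(dataset, alpha, window_lengths, params or MixtureParams(),
                             seed, dedup, znorm, early_exit, "s5m_threshold", tau=tau)


def _big_over(indices: Sequence[int], candidates, params: MixtureParams,
              rng: np.random.Generator) -> tuple[RepresentativeState, dict[int, int]]:
    state = RepresentativeState(params)
    cand_of: dict[int, int] = {}
    for cand_idx in indices:
        idx, accept = big_step(state, candidates[cand_idx].values, rng)
        if accept:
            cand_of[idx] = cand_idx
    return state, cand_of


def feature_selection_tarone(dataset: SeriesDataset, alpha: float = 0.05,
                             window_lengths: Iterable[int] = (),
                             params: MixtureParams | None = None, seed: int = 0,
                             dedup: bool = True, znorm: bool = False) -> MiningResult:
    """Representatives first (label-blind, extraction order), Tarone second."""
    t0 = time.perf_counter()
    params = params or MixtureParams()
    rng = np.random.default_rng(seed)
    candidates, p_min, theta, _ = _score_all(dataset, window_lengths, dedup, znorm)
    state, cand_of = _big_over(range(len(candidates)), candidates, params, rng)
    rep_cands = sorted(cand_of.values())
    if rep_cands:
        delta, testable = tarone_threshold(p_min[rep_cands], alpha)
        sig_idx = [c for c, t in zip(rep_cands, testable) if t]
    else:
        delta, sig_idx = alpha, []
    significant = [_scored(candidates, p_min, theta, c)
                   for c in sorted(sig_idx, key=lambda c: p_min[c])]
    return MiningResult(
        method="feature_selection_tarone", significant=significant, delta=delta,
        alpha=alpha, seed=seed, candidate_count=len(candidates),
        n_nonrepresentative=len(candidates) - len(rep_cands), params=params,
        window_lengths=tuple(sorted(set(int(w) for w in window_lengths))),
        runtime_seconds=time.perf_counter() - t0,
    )


def bonferroni_submodular(dataset: SeriesDataset, alpha: float = 0.05,
                          window_lengths: Iterable[int] = (),
                          params: MixtureParams | None = None, seed: int = 0,
                          dedup: bool = True, znorm: bool = False) -> MiningResult:
    """Bonferroni-significant candidates first, representative selection second."""
    t0 = time.perf_counter()
    params = params or MixtureParams()
    rng = np.random.default_rng(seed)
    candidates, p_min, theta, order = _score_all(dataset, window_lengths, dedup, znorm)
    delta = bonferroni_threshold(alpha, len(candidates), dataset.n)
    survivors = [c for c in order if p_min[c] < delta]
    state, cand_of = _big_over(survivors, candidates, params, rng)
    significant = [_scored(candidates, p_min, theta, cand_of[i])
                   for i in sorted(state.R_hat, key=lambda i: p_min[cand_of[i]])]
    return MiningResult(
        method="bonferroni_submodular", significant=significant, delta=delta,
        alpha=alpha, seed=seed, candidate_count=len(candidates),
        n_nonrepresentative=len(survivors) - len(state.R_hat), params=params,
        window_lengths=tuple(sorted(set(int(w) for w in window_lengths))),
        runtime_seconds=time.perf_counter() - t0,
    )


def tarone_submodular(dataset: SeriesDataset, alpha: float = 0.05,
                      window_lengths: Iterable[int] = (),
                      params: MixtureParams | None = None, seed: int = 0,
                      dedup: bool = True, znorm: bool = False) -> MiningResult:
    """Tarone-significant candidates first, representative selection second."""
    t0 = time.perf_counter()
    params = params or MixtureParams()
    rng = np.random.default_rng(seed)
    candidates, p_min, theta, order = _score_all(dataset, window_lengths, dedup, znorm)
    delta, testable = tarone_threshold(p_min, alpha)
    survivors = [c for c in order if testable[c]]
    state, cand_of = _big_over(survivors, candidates, params, rng)
    significant = [_scored(candidates, p_min, theta, cand_of[i])
                   for i in sorted(state.R_hat, key=lambda i: p_min[cand_of[i]])]
    return MiningResult(
        method="tarone_submodular", significant=significant, delta=delta,
        alpha=alpha, seed=seed, candidate_count=len(candidates),
        n_nonrepresentative=len(survivors) - len(state.R_hat), params=params,
        window_lengths=tuple(sorted(set(int(w) for w in window_lengths))),
        runtime_seconds=time.perf_counter() - t0,
    )


PIPELINES = {
    "s5m": s5m_mine,
    "s5m_threshold": s5m_threshold,
    "feature_selection_tarone": feature_selection_tarone,
    "bonferroni_submodular": bonferroni_submodular,
    "tarone_submodular": tarone_submodular,
}


def run_pipeline(method: str, dataset: SeriesDataset, **kwargs) -> MiningResult:
    """Dispatch a mining run by pipeline name."""
    try:
        fn = PIPELINES[method]
    except KeyError:
        raise ValueError(f"unknown pipeline {method!r}; choose from {sorted(PIPELINES)}")
    return fn(dataset, **kwargs)
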
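"""Representative-subset selectors over a similarity matrix.

Four selectors share the mixture objective of :mod:`s5m.submodular`:

* ``exhaustive_select`` — brute force over all subsets; the test oracle.
* ``greedy_select`` — classical greedy ascent.  Deliberately a *reference*
  implementation: each candidate step re-evaluates the published objective
  from scratch, including the quadratic pair sums, so its cost grows as
  O(k^2 n^3)-ish and it serves as the baseline the streaming optimizer is
  measured against.
* ``bidirectional_greedy_select`` — single randomized pass over a fixed
  ground set, keeping a growing set and a shrinking set and assigning each
  item with probability proportional to the clipped marginal gains.
* ``big_step`` — the streaming variant (bidirectional iterative greedy): the
  shrinking set starts *empty* and fills with discarded items, so items can
  arrive one at a time and the objective is maintained incrementally in O(n)
  per arrival.  This is the selector the mining loop interleaves with
  significance testing.

``threshold_select`` is the classical non-submodular baseline: an item becomes
a representative iff its similarity to every current representative is below a
cutoff tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .submodular import MixtureParams, RepresentativeState, mixture_objective

__all__ = [
    "OptimizerConfig",
    "exhaustive_select",
    "greedy_select",
    "bidirectional_greedy_select",
    "big_step",
    "big_select",
    "threshold_select",
]

_METHODS = ("exhaustive", "greedy", "bidirectional_greedy", "big", "threshold")


@dataclass(frozen=True)
class OptimizerConfig:
    method: str = "big"
    params: MixtureParams = field(default_factory=MixtureParams)
    seed: int = 0
    threshold_tau: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.threshold_tau is not None and not 0.0 < self.threshold_tau < 1.0:
            raise ValueError("threshold_tau must lie in (0, 1)")


def exhaustive_select(sim: np.ndarray, params: MixtureParams | None = None,
                      max_items: int = 14) -> list[int]:
    """Globally optimal subset by enumeration; refuses ground sets above ``max_items``.

    Ties are broken towards the smaller subset, then lexicographically.
    """
    params = params or MixtureParams()
    n = sim.shape[0]
    if n > max_items:
        raise ValueError(f"exhaustive search refused for |S| = {n} > {max_items}")
    S = list(range(n))
    best_val = -np.inf
    best: tuple[int, ...] = ()
    for size in range(n + 1):
        for R in combinations(S, size):
            val = mixture_objective(R, S, params, sim)
            if val > best_val + 1e-12:
                best_val, best = val, R
    return list(best)


def greedy_select(sim: np.ndarray, params: MixtureParams | None = None) -> list[int]:
    """Greedy ascent: repeatedly add the item with the best objective improvement.

    Stops when no remaining item improves the objective; ties go to the
    earliest item.  Each step evaluates the full objective from scratch (see
    module docstring).
    """
    params = params or MixtureParams()
    n = sim.shape[0]
    S = list(range(n))
    R: list[int] = []
    current = mixture_objective(R, S, params, sim)
    remaining = list(S)
    while remaining:
        gains = [mixture_objective(R + [x], S, params, sim) - current for x in remaining]
        best_pos = int(np.argmax(gains))
        if gains[best_pos] <= 1e-12:
            break
        current += gains[best_pos]
        R.append(remaining.pop(best_pos))
    return sorted(R)


def _ratio_probability(a: float, b: float) -> float:
    """Buchbinder acceptance probability a'/(a'+b') with clipped gains."""
    a = max(a, 0.0)
    b = max(b, 0.0)
    denom = a + b
    if not np.isfinite(denom) or denom <= 0.0:
        return 0.5
    return a / denom


def bidirectional_greedy_select(sim: np.ndarray, params: MixtureParams | None = None,
                                seed: int | np.random.Generator = 0) -> list[int]:
    """Randomized single pass over a fixed ground set (shrinking set starts full).

    Maintains a growing set R and a shrinking set B (initialized to S); each
    item is either committed to R or dropped from B with probability
    proportional to the clipped marginal gains of the two moves.
    """
    params = params or MixtureParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = sim.shape[0]
    S = list(range(n))
    R: list[int] = []
    B = list(S)
    for s in S:
        a = mixture_objective(R + [s], S, params, sim) - mixture_objective(R, S, params, sim)
        B_minus = [x for x in B if x != s]
        b = mixture_objective(B_minus, S, params, sim) - mixture_objective(B, S, params, sim)
        p = _ratio_probability(a, b)
        if rng.random() < p:
            R.append(s)
        else:
            B.remove(s)
    return sorted(R)


def big_step(state: RepresentativeState, values: np.ndarray,
             rng: np.random.Generator) -> tuple[int, bool]:
    """One arrival of the bidirectional iterative greedy optimizer.

    The new item is registered against the current ground set; the relative
    gains of making it a representative versus leaving it in the discard set
    are computed from the incremental caches, and the item is committed to one
    side with the clipped-ratio probability.  Returns (item index, became
    representative).
    """
    idx = state.add_item(values)
    f_R, f_Rs, f_B, f_Bs = state.side_values(idx)
    a = f_Rs - f_R        # gain of adding s to the representatives
    b = f_B - f_Bs        # gain of removing s again from the discard set
    p = _ratio_probability(a, b)
    accept = bool(rng.random() < p)
    state.assign(idx, to_representatives=accept)
    return idx, accept


def big_select(items: Sequence[np.ndarray], params: MixtureParams | None = None,
               seed: int | np.random.Generator = 0,
               state: RepresentativeState | None = None) -> list[int]:
    """Run the streaming optimizer over a whole sequence of items."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = state or RepresentativeState(params or MixtureParams())
    for values in items:
        big_step(state, values, rng)
    return list(state.R_hat)


def threshold_select(sim: np.ndarray, tau: float) -> list[int]:
    """Single pass in input order; keep an item iff sim to every kept item < tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    R: list[int] = []
    for s in range(sim.shape[0]):
        if all(sim[s, r] < tau for r in R):
            R.append(s)
    return R
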
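"""Submodular objectives for representative subset selection.

Given a ground set S of items with pairwise similarities in (0, 1], a
representative subset R is scored by a mixture of two submodular terms:

* facility location — mean, over items of S, of the best similarity to a
  representative (coverage; monotone nondecreasing in R);
* sum redundancy — total pairwise similarity over S minus the total pairwise
  similarity within R (diversity; monotone nonincreasing in R).

Pairwise sums range over ordered pairs including the diagonal (self-similarity
is 1), the cheapest convention to maintain incrementally; any consistent
convention gives f_sr(S) = 0.  The mixture adds a size term lambda_size * |R|.
Because the diagonal convention already charges (1 - lambda_mix) per added
representative through the redundancy term, a positive size term acts as a
per-item admission budget: an item improves the mixture only while its
similarity mass to the current representatives stays below
lambda_size - (1 - lambda_mix) plus its coverage gain.  ``size_term_sign``
flips the term into a pure penalty for users who want it.

:class:`RepresentativeState` maintains the growing representative set, the
discard set, the pairwise-similarity cache and running facility-location /
sum-redundancy terms so that a streaming optimizer pays O(processed items)
per step instead of recomputing the quadratic sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "MixtureParams",
    "RepresentativeState",
    "facility_location",
    "sum_redundancy",
    "mixture_objective",
    "pairwise_similarities",
]


@dataclass(frozen=True)
class MixtureParams:
    """Weights of the mixture objective.

    lambda_mix in [0, 1] trades facility location (coverage) against sum
    redundancy (diversity); lambda_size weights the size term.  Defaults 0.5
    and 1.0.
    """

    lambda_mix: float = 0.5
    lambda_size: float = 1.0
    size_term_sign: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")
        if self.size_term_sign not in (1, -1):
            raise ValueError("size_term_sign must be +1 or -1")


def facility_location(R: Sequence[int], S: Sequence[int], sim: np.ndarray) -> float:
    """Mean over s in S of max_{r in R} sim(s, r); empty R scores 0."""
    S = list(S)
    if not S:
        raise ValueError("S must be non-empty")
    R = list(R)
    if not R:
        return 0.0
    block = sim[np.ix_(S, R)]
    return float(block.max(axis=1).mean())


def sum_redundancy(R: Sequence[int], S: Sequence[int], sim: np.ndarray) -> float:
    """Total ordered-pair similarity over S minus the same total within R."""
    S = list(S)
    R = list(R)
    total = float(sim[np.ix_(S, S)].sum())
    within = float(sim[np.ix_(R, R)].sum()) if R else 0.0
    return total - within


def mixture_objective(R: Sequence[int], S: Sequence[int], params: MixtureParams,
                      sim: np.ndarray, norm: int | None = None) -> float:
    """Mixture of facility location, sum redundancy and the size term.

    ``norm`` overrides the facility-location normalizer |S| (used by streaming
    optimizers whose effective ground-set size differs from len(S)).
    """
    S = list(S)
    R = list(R)
    n = len(S) if norm is None else max(int(norm), 1)
    ffl = 0.0
    if R:
        ffl = float(sim[np.ix_(S, R)].max(axis=1).sum()) / n
    fsr = sum_redundancy(R, S, sim)
    size = params.size_term_sign * params.lambda_size * len(R)
    return params.lambda_mix * ffl + (1.0 - params.lambda_mix) * fsr + size


def _sims_to_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Similarity of one sequence to every row of an equal-length stack."""
    w, L = x.size, block.shape[1]
    if w == L:
        d = np.linalg.norm(block - x, axis=1)
    elif w < L:
        W = sliding_window_view(block, w, axis=1)
        sq = np.einsum("ijk,ijk->ij", W - x, W - x)
        d = np.sqrt(np.clip(sq.min(axis=1), 0.0, None))
    else:
        V = sliding_window_view(x, L)  # (w-L+1, L)
        sq = (
            np.einsum("ij,ij->i", V, V)[:, None]
            + np.einsum("ij,ij->i", block, block)[None, :]
            - 2.0 * V @ block.T
        )
        d = np.sqrt(np.clip(sq.min(axis=0), 0.0, None))
    return 1.0 / (1.0 + d)


def pairwise_similarities(items: Sequence[np.ndarray]) -> np.ndarray:
    """Full pairwise similarity matrix for a list of 1-D sequences."""
    n = len(items)
    sim = np.ones((n, n), dtype=float)
    by_len: dict[int, list[int]] = {}
    for i, it in enumerate(items):
        by_len.setdefault(len(it), []).append(i)
    groups = {L: np.stack([items[i] for i in idx]) for L, idx in by_len.items()}
    for i in range(n):
        x = np.asarray(items[i], dtype=float)
        for L, idx in by_len.items():
            row = _sims_to_block(x, groups[L])
            sim[i, idx] = row
    np.fill_diagonal(sim, 1.0)
    return (sim + sim.T) / 2.0  # exact symmetry despite float noise


class RepresentativeState:
    """Streaming state for representative subset selection.

    Items arrive one at a time; each processed item ends in exactly one of the
    representative set ``R_hat`` or the discard set ``B``.  The state caches

    * the pairwise similarity matrix over processed items (grown lazily),
    * per-item best similarity to ``R_hat`` and to ``B`` (facility-location
      numerators), and
    * running ordered-pair similarity totals (overall, within ``R_hat``,
      within ``B``),

    so objective deltas for a new item cost O(processed) work.  ``sim_calls``
    counts pairwise similarity evaluations, for complexity assertions.
    """

    def __init__(self, params: MixtureParams | None = None,
                 sim_func: Callable[[np.ndarray, np.ndarray], float] | None = None):
        self.params = params or MixtureParams()
        self._sim_func = sim_func
        self._items: list[np.ndarray] = []
        self._by_len: dict[int, list[int]] = {}
        self._sim = np.ones((16, 16), dtype=float)
        self.R_hat: list[int] = []
        self.B: list[int] = []
        self._best_R = np.zeros(16, dtype=float)
        self._best_B = np.zeros(16, dtype=float)
        self.sum_all = 0.0
        self.sum_RR = 0.0
        self.sum_BB = 0.0
        self.sim_calls = 0

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_processed(self) -> int:
        return len(self._items)

    def sim_matrix(self) -> np.ndarray:
        n = self.n_processed
        return self._sim[:n, :n]

    def _grow(self, n: int) -> None:
        cap = self._sim.shape[0]
        if n <= cap:
            return
        new_cap = max(2 * cap, n)
        sim = np.ones((new_cap, new_cap), dtype=float)
        sim[:cap, :cap] = self._sim
        self._sim = sim
        for name in ("_best_R", "_best_B"):
            arr = np.zeros(new_cap, dtype=float)
            old = getattr(self, name)
            arr[: old.size] = old
            setattr(self, name, arr)

    def _sim_row(self, x: np.ndarray, upto: int) -> np.ndarray:
        """Similarities of ``x`` to the first ``upto`` processed items."""
        row = np.empty(upto, dtype=float)
        if self._sim_func is not None:
            for j in range(upto):
                row[j] = self._sim_func(x, self._items[j])
        else:
            for L, idx in self._by_len.items():
                idx = [j for j in idx if j < upto]
                if not idx:
                    continue
                block = np.stack([self._items[j] for j in idx])
                row[idx] = _sims_to_block(x, block)
        self.sim_calls += upto
        return row

    def add_item(self, values: np.ndarray) -> int:
        """Register a new item; it belongs to neither set until assigned."""
        x = np.asarray(values, dtype=float)
        idx = self.n_processed
        self._grow(idx + 1)
        row = self._sim_row(x, idx)
        self._items.append(x)
        self._by_len.setdefault(x.size, []).append(idx)
        self._sim[idx, :idx] = row
        self._sim[:idx, idx] = row
        self._sim[idx, idx] = 1.0
        self.sum_all += 2.0 * row.sum() + 1.0
        self._best_R[idx] = row[self.R_hat].max() if self.R_hat else 0.0
        self._best_B[idx] = row[self.B].max() if self.B else 0.0
        return idx

    # -- objective evaluation ------------------------------------------------

    def _value(self, ffl_sum: float, within: float, size: int, norm: int) -> float:
        p = self.params
        ffl = ffl_sum / max(norm, 1)
        fsr = self.sum_all - within
        return p.lambda_mix * ffl + (1.0 - p.lambda_mix) * fsr \
            + p.size_term_sign * p.lambda_size * size

    def side_values(self, idx: int) -> tuple[float, float, float, float]:
        """Objective values (f_R, f_R+s, f_B, f_B+s) for the newly added item.

        The representative-side pair is normalized by the processed count N
        (the new item included); the discard-side pair by N - 1, reflecting
        that keeping the item out shrinks the effective ground set.
        """
        n = self.n_processed
        row = self._sim[idx, :n]
        best_R = self._best_R[:n]
        best_B = self._best_B[:n]

        f_R = self._value(best_R.sum(), self.sum_RR, len(self.R_hat), n)
        within_Rs = self.sum_RR + 2.0 * row[self.R_hat].sum() + 1.0
        f_Rs = self._value(np.maximum(best_R, row).sum(), within_Rs, len(self.R_hat) + 1, n)

        f_B = self._value(best_B.sum(), self.sum_BB, len(self.B), n - 1)
        within_Bs = self.sum_BB + 2.0 * row[self.B].sum() + 1.0
        f_Bs = self._value(np.maximum(best_B, row).sum(), within_Bs, len(self.B) + 1, n - 1)
        return f_R, f_Rs, f_B, f_Bs

    def assign(self, idx: int, to_representatives: bool) -> None:
        """Commit the new item to R_hat or B, updating caches incrementally."""
        n = self.n_processed
        row = self._sim[idx, :n]
        if to_representatives:
            self.sum_RR += 2.0 * row[self.R_hat].sum() + 1.0
            self.R_hat.append(idx)
            np.maximum(self._best_R[:n], row, out=self._best_R[:n])
        else:
            self.sum_BB += 2.0 * row[self.B].sum() + 1.0
            self.B.append(idx)
            np.maximum(self._best_B[:n], row, out=self._best_B[:n])

    def demote(self, idx: int) -> None:
        """Move a representative to the discard set (eviction); never reversed.

        The best-similarity cache for R_hat cannot be decremented, so it is
        rebuilt from the similarity matrix in O(|R_hat| * n).
        """
        self.R_hat.remove(idx)
        n = self.n_processed
        row = self._sim[idx, :n]
        self.sum_RR -= 2.0 * row[self.R_hat].sum() + 1.0
        if self.R_hat:
            self._best_R[:n] = self._sim[np.ix_(self.R_hat, range(n))].max(axis=0)
        else:
            self._best_R[:n] = 0.0
        self.sum_BB += 2.0 * row[self.B].sum() + 1.0
        self.B.append(idx)
        np.maximum(self._best_B[:n], row, out=self._best_B[:n])

    # -- from-scratch oracle (testing / verification) ------------------------

    def scratch_objective(self, R: Sequence[int], norm: int | None = None) -> float:
        """Recompute the mixture objective from the similarity matrix alone."""
        n = self.n_processed
        return mixture_objective(R, range(n), self.params, self.sim_matrix(),
                                 norm=n if norm is None else norm)

    def check_caches(self, rtol: float = 1e-9) -> None:
        """Assert that every cached quantity matches from-scratch recomputation."""
        n = self.n_processed
        sim = self.sim_matrix()
        assert np.isclose(self.sum_all, sim.sum(), rtol=rtol)
        assert np.isclose(self.sum_RR, sim[np.ix_(self.R_hat, self.R_hat)].sum()
                          if self.R_hat else 0.0, rtol=rtol)
        assert np.isclose(self.sum_BB, sim[np.ix_(self.B, self.B)].sum()
                          if self.B else 0.0, rtol=rtol)
        best_R = sim[:, self.R_hat].max(axis=1) if self.R_hat else np.zeros(n)
        best_B = sim[:, self.B].max(axis=1) if self.B else np.zeros(n)
        assert np.allclose(self._best_R[:n], best_R, rtol=rtol, atol=1e-12)
        assert np.allclose(self._best_B[:n], best_B, rtol=rtol, atol=1e-12)
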
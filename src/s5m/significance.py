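"""Association testing for shapelets: chi-squared p-values, per-shapelet
minimum p-values over all distance thresholds, and the Bonferroni and Tarone
corrected significance thresholds.

A shapelet ``s`` together with a distance threshold ``theta`` predicts label 1
for every series within distance ``theta``.  Cross-tabulating that prediction
against the true phenotype gives a 2x2 contingency table; its chi-squared
independence p-value measures the association.  The shapelet's score is the
minimum p-value over the thresholds induced by its observed distances to the
dataset; every observed distance generates one distinct split because
prediction uses ``<= theta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .data import SeriesDataset, ShapeletCandidate
from .distance import distance_profile

__all__ = [
    "ContingencyTable",
    "ScoredShapelet",
    "TaroneState",
    "contingency_table",
    "chi2_pvalue",
    "min_pvalue",
    "min_pvalues",
    "bonferroni_threshold",
    "tarone_threshold",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of shapelet prediction (rows: 1/0) against label (cols: 1/0).

    a: cases predicted 1, b: controls predicted 1,
    c: cases predicted 0, d: controls predicted 0.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ScoredShapelet:
    """A candidate with its minimum p-value and the threshold attaining it."""

    candidate: ShapeletCandidate
    p_min: float
    best_theta: float
    distances: np.ndarray | None = None


@dataclass
class TaroneState:
    """Target FWER, the current corrected threshold and the implied FWER estimate."""

    alpha: float
    delta_tar: float
    n_testable: int

    @property
    def alpha_hat(self) -> float:
        return self.delta_tar * self.n_testable


def contingency_table(shapelet: ShapeletCandidate, theta: float,
                      dataset: SeriesDataset) -> ContingencyTable:
    """Cross-tabulate the shapelet's prediction at ``theta`` against the labels."""
    dataset.require_both_classes()
    dists = distance_profile([shapelet], dataset)[0]
    labels = dataset.labels
    pred = dists <= theta
    a = int(np.sum(pred & (labels == 1)))
    b = int(np.sum(pred & (labels == 0)))
    c = int(np.sum(~pred & (labels == 1)))
    d = int(np.sum(~pred & (labels == 0)))
    return ContingencyTable(a, b, c, d)


def _chi2_sf(stat):
    return _chi2_dist.sf(stat, df=1)


def chi2_pvalue(table: ContingencyTable, yates: bool = False) -> float:
    """P-value of the 1-df chi-squared independence test.

    No continuity correction by default (matching the discrete-test framework
    the correction strategies assume); ``yates`` enables it.  Tables with an
    empty prediction margin (no series predicted 1, or all predicted 1) carry
    no split information and are defined to have p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    if a + c == 0 or b + d == 0:
        raise ValueError("both classes must be present")
    r1 = a + b
    r0 = c + d
    if r1 == 0 or r0 == 0:
        return 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff ** 2 / (r1 * r0 * (a + c) * (b + d))
    return float(_chi2_sf(stat))


def min_pvalues(dist_matrix: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized minimum p-value over observed-distance thresholds, per candidate.

    ``dist_matrix`` is (k, n): distance of candidate i to series j.  For each
    candidate, the threshold candidate set is its own observed distances
    (duplicates collapsed); ties in p are broken by the smallest threshold.
    Returns (p_min, best_theta) arrays of length k.
    """
    dist_matrix = np.atleast_2d(np.asarray(dist_matrix, dtype=float))
    labels = np.asarray(labels)
    n = labels.size
    n1 = int(labels.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(dist_matrix, axis=1, kind="stable")
    d_sorted = np.take_along_axis(dist_matrix, order, axis=1)
    lab_sorted = np.take_along_axis(np.broadcast_to(labels, dist_matrix.shape), order, axis=1)

    a = np.cumsum(lab_sorted, axis=1, dtype=np.int64)       # cases with dist <= theta
    r1 = np.arange(1, n + 1, dtype=np.int64)                # series predicted 1
    b = r1[None, :] - a
    c = n1 - a
    d = n0 - b
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1[None, :] * (n - r1)[None, :] * n1 * n0)
    p = _chi2_sf(stat)
    p[:, -1] = 1.0  # r0 = 0: degenerate prediction margin

    # duplicate distances collapse to one split: only the last occurrence of a
    # run of equal distances is a valid threshold
    valid = np.ones_like(p, dtype=bool)
    valid[:, :-1] = d_sorted[:, :-1] < d_sorted[:, 1:]
    p = np.where(valid, p, np.inf)

    best = np.argmin(p, axis=1)  # first minimum = smallest theta (rows sorted)
    p_min = np.minimum(p[np.arange(p.shape[0]), best], 1.0)
    best_theta = d_sorted[np.arange(p.shape[0]), best]
    return p_min, best_theta


def min_pvalue(shapelet: ShapeletCandidate, dataset: SeriesDataset,
               keep_distances: bool = True) -> ScoredShapelet:
    """Score one shapelet: minimum chi-squared p-value over all observed thresholds."""
    dataset.require_both_classes()
    dists = distance_profile([shapelet], dataset)
    p_min, theta = min_pvalues(dists, dataset.labels)
    return ScoredShapelet(
        candidate=shapelet,
        p_min=float(p_min[0]),
        best_theta=float(theta[0]),
        distances=dists[0] if keep_distances else None,
    )


def bonferroni_threshold(alpha: float, n_candidates: int, n: int) -> float:
    """Bonferroni-corrected threshold alpha / (|C| * n): n thresholds per candidate."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_candidates <= 0 or n <= 0:
        raise ValueError("candidate and series counts must be positive")
    return alpha / (n_candidates * n)


def tarone_threshold(p_mins: Sequence[float], alpha: float) -> tuple[float, np.ndarray]:
    """Tarone's corrected threshold over a collection of minimum p-values.

    Returns the largest delta of the form alpha/k (k a positive integer) such
    that at most k of the p-values fall strictly below delta — the fixed point
    reached by lowering delta from alpha — together with the boolean mask of
    testable candidates (p < delta).
    """
    p = np.asarray(p_mins, dtype=float)
    if p.size == 0:
        raise ValueError("p_mins must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p_sorted = np.sort(p)
    k = 1
    while True:
        delta = alpha / k
        count = int(np.searchsorted(p_sorted, delta, side="left"))  # strict <
        if count <= k:
            return delta, p < delta
        k += 1
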
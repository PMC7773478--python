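"""Scoring retrieved shapelet sets against ground-truth prototypes.

Each retrieved shapelet is mapped to its most similar ground-truth prototype;
the number of correctly detected prototypes k_d is the size of the image of
that map.  Then

    recall    = k_d / |R|,      precision = k_d / |R_hat|,
    F1        = 2 P R / (P + R),

and min_sim is the minimum, over retrieved shapelets, of the similarity to
the matched prototype — the worst-case retrieval fidelity.  Degenerate cases
(empty retrieval, k_d = 0) score 0 rather than erroring, so broken runs rank
worst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .distance import similarity

__all__ = [
    "EvaluationReport",
    "match_retrieved",
    "prf1",
    "min_sim",
    "evaluate_retrieval",
    "shapelet_set_stats",
    "compare_methods",
]


@dataclass(frozen=True)
class EvaluationReport:
    k_d: int
    precision: float
    recall: float
    f1: float
    min_sim: float
    n_retrieved: int
    n_truth: int
    per_prototype_hits: dict = field(default_factory=dict)


def match_retrieved(retrieved: Sequence[np.ndarray],
                    truth: Sequence[np.ndarray]) -> dict[int, int]:
    """Map retrieved-shapelet index -> argmax-similarity prototype index.

    Ties go to the lowest prototype index.
    """
    if not truth:
        raise ValueError("ground-truth set must be non-empty")
    mapping: dict[int, int] = {}
    for i, shp in enumerate(retrieved):
        sims = np.array([similarity(shp, proto) for proto in truth])
        mapping[i] = int(np.argmax(sims))  # argmax returns the first maximum
    return mapping


def prf1(k_d: int, n_truth: int, n_retrieved: int) -> tuple[float, float, float]:
    """Precision, recall and F1 with the zero conventions for degenerate runs."""
    if n_truth <= 0:
        raise ValueError("n_truth must be positive")
    recall = k_d / n_truth
    precision = k_d / n_retrieved if n_retrieved > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def min_sim(retrieved: Sequence[np.ndarray], truth: Sequence[np.ndarray]) -> float:
    """Minimum over retrieved shapelets of the similarity to the closest prototype."""
    if not retrieved:
        return 0.0
    return min(max(similarity(shp, proto) for proto in truth) for shp in retrieved)


def evaluate_retrieval(retrieved: Sequence[np.ndarray],
                       truth: Sequence[np.ndarray]) -> EvaluationReport:
    """Full report: matching, k_d, precision/recall/F1 and min_sim."""
    mapping = match_retrieved(retrieved, truth) if retrieved else {}
    hits: dict[int, list[int]] = {}
    for shp_idx, proto_idx in mapping.items():
        hits.setdefault(proto_idx, []).append(shp_idx)
    k_d = len(hits)
    precision, recall, f1 = prf1(k_d, len(truth), len(retrieved))
    return EvaluationReport(
        k_d=k_d, precision=precision, recall=recall, f1=f1,
        min_sim=min_sim(retrieved, truth),
        n_retrieved=len(retrieved), n_truth=len(truth),
        per_prototype_hits=hits,
    )


def shapelet_set_stats(retrieved: Sequence[np.ndarray],
                       p_values: Sequence[float] | None = None) -> dict:
    """Structural summary of a retrieved set.

    Within-shapelet variances (flat shapelets score 0), all pairwise
    similarities among the set, and — when p-values are supplied — their
    base-10 logarithms.
    """
    variances = [float(np.var(np.asarray(s, dtype=float))) for s in retrieved]
    pairwise = [similarity(retrieved[i], retrieved[j])
                for i in range(len(retrieved)) for j in range(i + 1, len(retrieved))]
    out = {"within_variance": variances, "pairwise_similarity": pairwise}
    if p_values is not None:
        out["log10_p"] = [float(np.log10(max(p, np.finfo(float).tiny))) for p in p_values]
    return out


def compare_methods(scores_a: Sequence[float],
                    scores_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test on per-repetition scores.

    Returns (statistic, two-sided p).  Identical constant samples give
    (0.0, 1.0); single-observation groups are rejected (undefined df).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least two observations per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 0.0, 1.0
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)
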
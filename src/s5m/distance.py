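"""Shapelet distance, similarity transform, prediction and candidate extraction.

The distance between two sequences of possibly unequal length is the minimum
Euclidean distance over all alignments of the shorter sequence slid along the
longer one,

    dist(r, s) = min_j ( sum_k (s[j+k] - r[k])^2 )^(1/2),

and similarity is the bounded transform sim(r, s) = 1 / (1 + dist(r, s)),
which equals 1 exactly when the shorter sequence occurs verbatim in the
longer.  Values are compared raw: levels of clinical scores and vital signs
carry meaning, so no per-window z-normalization is applied by default.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data import LabeledSeries, SeriesDataset, ShapeletCandidate

__all__ = [
    "min_euclidean_distance",
    "similarity",
    "predict",
    "extract_candidates",
    "distance_profile",
    "znormalize",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    return arr


def min_euclidean_distance(r, s) -> float:
    """Minimum Euclidean distance of the shorter sequence slid along the longer.

    Arguments may be passed in either order; the shorter/longer roles are
    assigned internally.  Equal-length inputs have exactly one alignment, so
    the result is the plain Euclidean norm of the difference.
    """
    r = _as_1d(r, "r")
    s = _as_1d(s, "s")
    if r.size > s.size:
        r, s = s, r
    if r.size == s.size:
        return float(np.linalg.norm(s - r))
    windows = sliding_window_view(s, r.size)
    sq = np.einsum("ij,ij->i", windows - r, windows - r)
    return float(np.sqrt(sq.min()))


def similarity(r, s) -> float:
    """Similarity transform ``1 / (1 + dist(r, s))``, in (0, 1]."""
    return 1.0 / (1.0 + min_euclidean_distance(r, s))


def predict(shapelet: ShapeletCandidate | Sequence[float], theta: float,
            t: LabeledSeries | Sequence[float]) -> int:
    """Predict the label of series ``t``: 1 iff the shapelet occurs within ``theta``.

    The semantics are directional ("the shapelet occurs in the series"), so the
    shapelet must not be longer than the series.
    """
    s = shapelet.values if isinstance(shapelet, ShapeletCandidate) else _as_1d(shapelet, "shapelet")
    values = t.values if isinstance(t, LabeledSeries) else _as_1d(t, "t")
    if len(s) > len(values):
        raise ValueError(
            f"shapelet of length {len(s)} cannot be matched inside a series of length {len(values)}"
        )
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return int(min_euclidean_distance(s, values) <= theta)


def znormalize(values: np.ndarray) -> np.ndarray:
    """Per-window z-normalization; constant windows map to zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def extract_candidates(
    dataset: SeriesDataset,
    window_lengths: Iterable[int],
    dedup: bool = False,
    znorm: bool = False,
) -> list[ShapeletCandidate]:
    """Sliding-window candidate extraction over every series and window width.

    For each series of length m and each width w <= m, all m - w + 1 contiguous
    windows are emitted, ordered by series, then width ascending, then start
    offset ascending.  With ``dedup``, candidates with identical value
    sequences collapse to their first occurrence — repeated identical
    subsequences add no statistical information and only inflate the
    multiple-testing burden.
    """
    widths = sorted(set(int(w) for w in window_lengths))
    if not widths:
        raise ValueError("window_lengths must be non-empty")
    if widths[0] < 2:
        raise ValueError("window lengths must be >= 2")
    if widths[-1] > dataset.max_length():
        raise ValueError(
            f"window length {widths[-1]} exceeds the longest series ({dataset.max_length()})"
        )
    out: list[ShapeletCandidate] = []
    seen: set[tuple[float, ...]] = set()
    for series in dataset:
        values = series.values
        for w in widths:
            if w > values.size:
                continue
            windows = sliding_window_view(values, w)
            for start in range(windows.shape[0]):
                vals = windows[start]
                if znorm:
                    vals = znormalize(vals)
                cand = ShapeletCandidate(values=np.array(vals), source_id=series.id, start=start)
                if dedup:
                    k = cand.key()
                    if k in seen:
                        continue
                    seen.add(k)
                out.append(cand)
    return out


def distance_profile(candidates: Sequence[ShapeletCandidate],
                     dataset: SeriesDataset) -> np.ndarray:
    """Distance of every candidate to every series, as a (k, n) matrix.

    Vectorized per (candidate width, series length) group; the shorter of the
    two sequences is always slid along the longer, so ragged datasets are
    supported without error.
    """
    k = len(candidates)
    n = dataset.n
    dists = np.empty((k, n), dtype=float)

    by_width: dict[int, list[int]] = {}
    for idx, cand in enumerate(candidates):
        by_width.setdefault(cand.length, []).append(idx)
    by_length: dict[int, list[int]] = {}
    for j, series in enumerate(dataset):
        by_length.setdefault(len(series), []).append(j)

    for w, cand_idx in by_width.items():
        C = np.stack([candidates[i].values for i in cand_idx])  # (kc, w)
        c_sq = np.einsum("ij,ij->i", C, C)
        for m, series_idx in by_length.items():
            S = np.stack([dataset.series[j].values for j in series_idx])  # (ns, m)
            if w <= m:
                # slide candidates along series: windows (ns, m-w+1, w)
                W = sliding_window_view(S, w, axis=1)
                w_sq = np.einsum("ijk,ijk->ij", W, W)
                cross = np.einsum("ik,ljk->ilj", C, W)  # (kc, ns, nwin)
                sq = c_sq[:, None, None] + w_sq[None, :, :] - 2.0 * cross
                block = np.sqrt(np.clip(sq.min(axis=2), 0.0, None))
            else:
                # series shorter than the candidate: slide series along candidate
                V = sliding_window_view(C, m, axis=1)  # (kc, w-m+1, m)
                v_sq = np.einsum("ijk,ijk->ij", V, V)
                s_sq = np.einsum("ij,ij->i", S, S)
                cross = np.einsum("ijk,lk->ijl", V, S)  # (kc, nwin, ns)
                sq = v_sq[:, :, None] + s_sq[None, None, :] - 2.0 * cross
                block = np.sqrt(np.clip(sq.min(axis=1), 0.0, None))
            dists[np.ix_(cand_idx, series_idx)] = block
    return dists
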
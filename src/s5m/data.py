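"""Containers for labeled time series and shapelet candidates.

A dataset is an ordered collection of real-valued series, each carrying a
binary phenotype label (1 = case, 0 = control).  Series may have different
lengths; a shapelet candidate is a contiguous window cut from one of them,
with provenance (source series, start offset, width) retained so that mined
patterns can be traced back to the record they came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledSeries", "SeriesDataset", "ShapeletCandidate"]


@dataclass(frozen=True)
class LabeledSeries:
    """A single time series with a binary phenotype label."""

    values: np.ndarray
    label: int
    id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("series values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.id!r} contains non-finite values")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "label", int(self.label))

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SeriesDataset:
    """An ordered collection of :class:`LabeledSeries`."""

    series: tuple[LabeledSeries, ...]

    def __post_init__(self) -> None:
        series = tuple(self.series)
        if len(series) < 2:
            raise ValueError("a dataset needs at least two series")
        object.__setattr__(self, "series", series)

    @property
    def n(self) -> int:
        return len(self.series)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.series], dtype=np.int64)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def require_both_classes(self) -> None:
        """Raise unless both labels occur (statistical tests are undefined otherwise)."""
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("dataset must contain both case (1) and control (0) series")

    def max_length(self) -> int:
        return max(len(s) for s in self.series)

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class ShapeletCandidate:
    """A contiguous window of a source series, 0-based half-open [start, start+length)."""

    values: np.ndarray
    source_id: str = ""
    start: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a shapelet candidate needs at least two values")
        object.__setattr__(self, "values", values)

    @property
    def length(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.length

    def key(self) -> tuple[float, ...]:
        """Hashable value signature, used for deduplication."""
        return tuple(self.values.tolist())
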
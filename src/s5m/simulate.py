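"""Synthetic benchmark generators with known ground truth.

Two designs, both built on five fixed prototype subsequences:

* **Replicate sets** — every sequence is one prototype plus i.i.d.
  Uniform(-sigma, sigma) noise; used for comparing subset-selection
  optimizers, where the ground truth *is* the prototype set.
* **Planted-shapelet classification** — case series are uniform-noise
  backgrounds of length m (default 20) with one noisy prototype injected at a
  random offset; control series are pure uniform noise.  The generator
  records, for each case, which prototype went where, so retrieval can be
  scored against the ground truth.

The five default prototypes are canonical qualitative shapes — ramp up, ramp
down, peak, valley, step — of length 7 with amplitude +-2.  The amplitude is
calibrated so the noise grid {1, 2, 5} spans the regimes of the benchmark:
comfortable detection at sigma = 1, borderline at sigma = 2 (a Bonferroni
correction starts to miss), and weak signal at sigma = 5 (per-candidate
p-values straddle the corrected thresholds, so the multiplicity strategy
decides what is found).  They are ordinary data, not magic constants: pass
your own prototypes to study other shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import LabeledSeries, SeriesDataset

__all__ = [
    "SimulationSpec",
    "Annotation",
    "make_prototype_set",
    "generate_replicates",
    "generate_labeled_dataset",
]

_PROTO_LENGTH = 7
_PROTO_AMPLITUDE = 2.0


def make_prototype_set(seed: int | None = None, length: int = _PROTO_LENGTH,
                       amplitude: float = _PROTO_AMPLITUDE) -> list[np.ndarray]:
    """Five structurally distinct prototype subsequences.

    Deterministic: ramp up, ramp down, peak, valley and step, each of the
    given length with values in [-amplitude, amplitude].  A seed adds a small
    reproducible jitter (2% of amplitude) so that independent studies can use
    distinct but equally shaped prototypes; ``seed=None`` returns the
    canonical shapes exactly.
    """
    if length < 3:
        raise ValueError("prototypes need length >= 3")
    half = (length + 1) // 2
    up = np.linspace(-amplitude, amplitude, length)
    peak_rise = np.linspace(-amplitude, amplitude, half)
    peak = np.concatenate([peak_rise, peak_rise[-2 if length % 2 else -1 :: -1][: length - half]])
    step = np.full(length, -amplitude)
    step[length // 2:] = amplitude
    prototypes = [up, up[::-1].copy(), peak, -peak, step]
    if seed is not None:
        rng = np.random.default_rng(seed)
        jitter = 0.02 * amplitude
        prototypes = [p + rng.uniform(-jitter, jitter, size=length) for p in prototypes]
    return [np.asarray(p, dtype=float) for p in prototypes]


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of the planted-shapelet classification design."""

    n_series: int = 100
    sigma: float = 1.0
    series_length: int = 20
    case_fraction: float = 0.5
    seed: int = 0
    prototypes: tuple = field(default_factory=lambda: tuple(make_prototype_set()))

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        protos = tuple(np.asarray(p, dtype=float) for p in self.prototypes)
        if not protos:
            raise ValueError("at least one prototype is required")
        if max(p.size for p in protos) > self.series_length:
            raise ValueError("prototype longer than the series length")
        object.__setattr__(self, "prototypes", protos)

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Annotation:
    """Ground-truth record for one case series."""

    series_id: str
    prototype_index: int
    offset: int
    length: int


def generate_replicates(prototypes=None, n_per_prototype: int = 10,
                        sigma: float = 1.0, seed: int = 0) -> list[np.ndarray]:
    """Noisy replicates: each output is one prototype plus Uniform(-sigma, sigma) noise."""
    if n_per_prototype <= 0:
        raise ValueError("n_per_prototype must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    prototypes = [np.asarray(p, float) for p in (prototypes or make_prototype_set())]
    rng = np.random.default_rng(seed)
    out = []
    for proto in prototypes:
        for _ in range(n_per_prototype):
            out.append(proto + rng.uniform(-sigma, sigma, size=proto.size))
    return out


def generate_labeled_dataset(spec: SimulationSpec) -> tuple[SeriesDataset, list[Annotation]]:
    """Planted-shapelet dataset plus the injection ground truth.

    Cases (label 1) are uniform-noise backgrounds with one noisy prototype
    overwriting a random window; controls (label 0) are pure uniform noise.
    Prototype noise and background noise share the same amplitude sigma.
    """
    rng = np.random.default_rng(spec.seed)
    n_cases = int(round(spec.n_series * spec.case_fraction))
    n_controls = spec.n_series - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValueError("spec yields a single-class dataset")
    m = spec.series_length
    series: list[LabeledSeries] = []
    annotations: list[Annotation] = []
    for i in range(n_cases):
        sid = f"case-{i}"
        background = rng.uniform(-spec.sigma, spec.sigma, size=m)
        proto_idx = int(rng.integers(len(spec.prototypes)))
        proto = spec.prototypes[proto_idx]
        offset = int(rng.integers(m - proto.size + 1))
        noisy = proto + rng.uniform(-spec.sigma, spec.sigma, size=proto.size)
        background[offset: offset + proto.size] = noisy
        series.append(LabeledSeries(values=background, label=1, id=sid))
        annotations.append(Annotation(series_id=sid, prototype_index=proto_idx,
                                      offset=offset, length=int(proto.size)))
    for i in range(n_controls):
        values = rng.uniform(-spec.sigma, spec.sigma, size=m)
        series.append(LabeledSeries(values=values, label=0, id=f"control-{i}"))
    return SeriesDataset(series=tuple(series)), annotations
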
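"""Reading labeled series from delimited text and (de)serializing results.

Dataset format: one series per row, first field the binary label (0/1), the
remaining fields real values.  Comma, tab or whitespace delimiters are
auto-detected; rows may have different lengths; trailing empty or NaN fields
are ignored.  Results round-trip through JSON;
wall-time metadata stays in memory so result files are bit-reproducible per seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .data import LabeledSeries, SeriesDataset, ShapeletCandidate
from .mining import MiningResult
from .significance import ScoredShapelet
from .simulate import Annotation
from .submodular import MixtureParams

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_result",
    "read_result",
    "write_annotations",
    "read_annotations",
]


def _split_row(line: str) -> list[str]:
    for delim in (",", "\t"):
        if delim in line:
            return [f.strip() for f in line.split(delim)]
    return line.split()


def read_dataset(path: str | Path) -> SeriesDataset:
    """Parse a label-first delimited text file into a dataset."""
    path = Path(path)
    series: list[LabeledSeries] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            label_txt, value_txt = fields[0], fields[1:]
            try:
                label_f = float(label_txt)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: label {label_txt!r} is not numeric")
            if label_f not in (0.0, 1.0):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label_txt!r}")
            values = []
            for pos, txt in enumerate(value_txt, start=2):
                if txt == "":
                    continue
                try:
                    v = float(txt)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: field {pos} ({txt!r}) is not numeric")
                if math.isnan(v):
                    continue
                values.append(v)
            if not values:
                raise ValueError(f"{path}:{lineno}: series has no values")
            series.append(LabeledSeries(values=np.array(values), label=int(label_f),
                                        id=f"row-{lineno}"))
    if len(series) < 2:
        raise ValueError(f"{path}: expected at least two series, found {len(series)}")
    return SeriesDataset(series=tuple(series))


def write_dataset(dataset: SeriesDataset, path: str | Path, delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in dataset:
            fields = [str(s.label)] + [repr(v) for v in s.values.tolist()]
            fh.write(delimiter.join(fields) + "\n")


def _shapelet_to_dict(s: ScoredShapelet) -> dict:
    return {
        "values": s.candidate.values.tolist(),
        "source_id": s.candidate.source_id,
        "start": s.candidate.start,
        "length": s.candidate.length,
        "p_min": s.p_min,
        "best_theta": s.best_theta,
    }


def _shapelet_from_dict(d: dict) -> ScoredShapelet:
    cand = ShapeletCandidate(values=np.array(d["values"], dtype=float),
                             source_id=d["source_id"], start=int(d["start"]))
    return ScoredShapelet(candidate=cand, p_min=float(d["p_min"]),
                          best_theta=float(d["best_theta"]))


def write_result(result: MiningResult, path: str | Path) -> None:
    """Serialize a mining result (config echo included) as JSON."""
    doc = {
        "method": result.method,
        "alpha": result.alpha,
        "seed": result.seed,
        "delta": result.delta,
        "candidate_count": result.candidate_count,
        "n_nonrepresentative": result.n_nonrepresentative,
        "n_evicted": result.n_evicted,
        "n_pruned_early": result.n_pruned_early,
        "threshold_tau": result.threshold_tau,
        "window_lengths": list(result.window_lengths),
        "params": {
            "lambda_mix": result.params.lambda_mix,
            "lambda_size": result.params.lambda_size,
            "size_term_sign": result.params.size_term_sign,
        },
        "significant": [_shapelet_to_dict(s) for s in result.significant],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_result(path: str | Path) -> MiningResult:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    params = MixtureParams(**doc["params"])
    return MiningResult(
        method=doc["method"],
        significant=[_shapelet_from_dict(d) for d in doc["significant"]],
        delta=float(doc["delta"]),
        alpha=float(doc["alpha"]),
        seed=int(doc["seed"]),
        candidate_count=int(doc["candidate_count"]),
        n_nonrepresentative=int(doc["n_nonrepresentative"]),
        n_evicted=int(doc["n_evicted"]),
        n_pruned_early=int(doc["n_pruned_early"]),
        threshold_tau=doc["threshold_tau"],
        params=params,
        window_lengths=tuple(doc["window_lengths"]),
    )


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    doc = [
        {"series_id": a.series_id, "prototype_index": a.prototype_index,
         "offset": a.offset, "length": a.length}
        for a in annotations
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_annotations(path: str | Path) -> list[Annotation]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [Annotation(series_id=d["series_id"], prototype_index=int(d["prototype_index"]),
                       offset=int(d["offset"]), length=int(d["length"])) for d in doc]
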
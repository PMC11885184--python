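"""Detection evaluation: matching against ground truth and summary metrics.

Detections are matched to annotated cells one-to-one by a greedy
nearest-first rule, then summarized with the standard detection metrics

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F         = 2 * precision * recall / (precision + recall)
    accuracy  = tp / (tp + fp + fn)

A pure detection task has no natural true-negative count, so "accuracy" is
the Jaccard-style detection accuracy above; note that whenever fp = 0 it
coincides with recall.  Metrics with a zero denominator are reported as
undefined (``None``), never coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .detection import Blob

__all__ = [
    "GroundTruthCell",
    "MatchResult",
    "EvalReport",
    "match_detections",
    "compute_metrics",
    "f_measure",
    "per_frame_counts",
]

#: Default center-distance gate (pixels) when truth radii are not used.
DEFAULT_MATCH_DIST = 10.0


@dataclass(frozen=True)
class GroundTruthCell:
    """An annotated cell: center (x, y) in pixels and an optional radius."""

    x: float
    y: float
    radius: Optional[float] = None


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    #: accepted (blob_index, truth_index) pairs
    pairing: tuple[tuple[int, int], ...]


@dataclass
class EvalReport:
    """TP/FP/FN counts with derived metrics; ``None`` marks an undefined metric."""

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]
    accuracy: Optional[float]
    per_frame: list[tuple[int, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        def fmt(v: Optional[float]):
            return "N/A" if v is None else v

        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": fmt(self.precision),
            "recall": fmt(self.recall),
            "f_measure": fmt(self.f_measure),
            "accuracy": fmt(self.accuracy),
            "per_frame": [
                {"frame": f, "cells_detected": c, "segments_extracted": s}
                for f, c, s in self.per_frame
            ],
        }


def match_detections(
    blobs: Sequence[Blob],
    truth: Sequence[GroundTruthCell],
    match_dist: Union[float, str] = DEFAULT_MATCH_DIST,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground truth.

    Candidate (blob, truth) pairs are sorted by center distance ascending
    (ties broken by truth index then blob index, so the result is
    deterministic) and accepted when the distance is within the gate and
    neither member is already matched.  The gate is either a fixed pixel
    distance or, with ``match_dist="radius"``, each truth cell's own radius.
    """
    use_radius = isinstance(match_dist, str)
    if use_radius and match_dist != "radius":
        raise ValueError("match_dist must be a number or the string 'radius'")

    candidates = []
    for ti, cell in enumerate(truth):
        gate = cell.radius if use_radius else float(match_dist)
        if gate is None:
            gate = DEFAULT_MATCH_DIST
        for bi, blob in enumerate(blobs):
            d = math.hypot(blob.x - cell.x, blob.y - cell.y)
            if d <= gate:
                candidates.append((d, ti, bi))
    candidates.sort()

    matched_blobs: set[int] = set()
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for d, ti, bi in candidates:
        if ti in matched_truth or bi in matched_blobs:
            continue
        matched_truth.add(ti)
        matched_blobs.add(bi)
        pairs.append((bi, ti))

    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(blobs) - tp,
        fn=len(truth) - tp,
        pairing=tuple(sorted(pairs)),
    )


def f_measure(precision: float, recall: float) -> Optional[float]:
    """Harmonic mean of precision and recall (scale-invariant: works on
    fractions or percentages alike).  ``None`` when both are zero."""
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(tp: int, fp: int, fn: int) -> EvalReport:
    """Precision/recall/F/accuracy from counts; zero-denominator metrics are
    ``None``."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f = None
    if precision is not None and recall is not None:
        f = f_measure(precision, recall)
    accuracy = tp / (tp + fp + fn) if tp + fp + fn > 0 else None
    return EvalReport(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f_measure=f, accuracy=accuracy,
    )


def per_frame_counts(
    frame_results: Sequence[tuple[int, Sequence, Sequence]],
) -> list[tuple[int, int, int]]:
    """(frame_index, n_cells_detected, n_segments_extracted) per frame.

    ``frame_results`` holds (frame_index, blobs, segments) triples; segment
    counts can only be <= blob counts because clipping may drop crops.
    """
    records = []
    for frame_index, blobs, segments in frame_results:
        n_cells, n_segments = len(blobs), len(segments)
        if n_segments > n_cells:
            raise ValueError(
                f"frame {frame_index}: more segments ({n_segments}) than "
                f"detections ({n_cells})"
            )
        records.append((int(frame_index), n_cells, n_segments))
    return records
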
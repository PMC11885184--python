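"""Scale-space extremum selection and overlap pruning.

A detection is a voxel of the normalized-LoG volume that is strictly greater
than all 26 neighbors in its 3x3x3 (scale, y, x) neighborhood, so location
and scale are selected simultaneously.  Surviving voxels become blobs with
radius r = sqrt(2) * sigma_hat, then greedy non-maximum suppression removes
lower-response blobs whose disc overlaps a kept disc too much.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .scale_space import ScaleSpace, SigmaSchedule, build_scale_space, to_grayscale

__all__ = [
    "RADIUS_PER_SIGMA",
    "Blob",
    "DetectionConfig",
    "find_scale_space_extrema",
    "prune_overlaps",
    "detect",
    "circle_intersection_area",
    "disc_overlap_fraction",
]

#: Conversion from detected scale to effective disc radius, r = sqrt(2) * sigma.
RADIUS_PER_SIGMA = math.sqrt(2.0)


@dataclass(frozen=True)
class Blob:
    """A detected interest point (x_hat, y_hat, sigma_hat).

    Coordinates are 0-based pixel centers: ``x`` is the column, ``y`` the
    row.  ``radius`` is always ``sqrt(2) * sigma``; ``response`` is the
    normalized-LoG value at the extremum (after any polarity flip, so larger
    is always stronger).
    """

    x: float
    y: float
    sigma: float
    response: float
    polarity: str = "dark"
    radius: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("blob sigma must be positive")
        object.__setattr__(self, "radius", RADIUS_PER_SIGMA * self.sigma)

    def to_record(self, frame: int = 0) -> dict:
        return {
            "frame": frame,
            "x": self.x,
            "y": self.y,
            "sigma": self.sigma,
            "radius": self.radius,
            "response": self.response,
            "polarity": self.polarity,
        }


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholding and suppression parameters for the extremum search.

    threshold_rel
        Keep only voxels with response >= threshold_rel * (volume maximum),
        in (0, 1].  Relative thresholding adapts to the wide stain-intensity
        variation seen across cytology fields.
    threshold_abs
        Optional absolute response floor, applied in addition.
    overlap_max
        Maximum allowed pairwise overlap, measured as the fraction of the
        smaller disc's area covered by the intersection, in [0, 1).
    neighborhood
        Only ``"full26"`` (the complete 3x3x3 neighborhood) is supported.
    """

    threshold_rel: float = 0.1
    threshold_abs: Optional[float] = None
    overlap_max: float = 0.5
    neighborhood: str = "full26"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_rel <= 1.0):
            raise ValueError("threshold_rel must lie in (0, 1]")
        if not (0.0 <= self.overlap_max < 1.0):
            raise ValueError("overlap_max must lie in [0, 1)")
        if self.neighborhood != "full26":
            raise ValueError("only the full 26-neighbor comparison is supported")


_FOOTPRINT = np.ones((3, 3, 3), dtype=bool)
_FOOTPRINT[1, 1, 1] = False

#: Responses below this are numerical noise on the [0, 1] intensity scale
#: (constant-input annihilation holds to ~1e-9) and never mark a blob.
MIN_RESPONSE = 1e-9


def _blob_sort_key(b: Blob) -> tuple:
    # Descending response; ties broken lexicographically by (y, x, sigma)
    # for deterministic output.
    return (-b.response, b.y, b.x, b.sigma)


def find_scale_space_extrema(
    volume: ScaleSpace, config: DetectionConfig | None = None
) -> list[Blob]:
    """All voxels at least as large as their 26 scale-space neighbors.

    Only interior scales are eligible (an extremum needs a scale neighbor on
    both sides) and the 1-pixel spatial border is excluded.  Candidates must
    be positive and pass the configured relative/absolute thresholds.  Blobs
    are returned ordered by descending response.

    The comparison is non-strict so that exact response plateaus — which
    arise systematically when an image is upsampled by pixel replication and
    a symmetric peak straddles the grid — still yield candidates; plateau
    duplicates share one response value and are collapsed deterministically
    by :func:`prune_overlaps`.  On volumes without ties this is identical to
    the strict comparison.
    """
    config = config or DetectionConfig()
    resp = volume.responses
    if resp.shape[0] < 3:
        raise ValueError("scale-space volume needs at least 3 scale layers")

    neighbor_max = ndimage.maximum_filter(
        resp, footprint=_FOOTPRINT, mode="constant", cval=-np.inf
    )
    mask = resp >= neighbor_max
    # extrema over scale require interior scale layers
    mask[0] = False
    mask[-1] = False
    # exclude the 1-pixel spatial border
    mask[:, 0, :] = False
    mask[:, -1, :] = False
    mask[:, :, 0] = False
    mask[:, :, -1] = False

    threshold = MIN_RESPONSE
    vmax = float(resp.max(initial=-np.inf))
    if vmax > MIN_RESPONSE:
        threshold = max(threshold, config.threshold_rel * vmax)
    if config.threshold_abs is not None:
        threshold = max(threshold, config.threshold_abs)
    mask &= resp >= threshold

    ks, ys, xs = np.nonzero(mask)
    blobs = [
        Blob(
            x=float(x),
            y=float(y),
            sigma=volume.schedule[int(k)],
            response=float(resp[k, y, x]),
            polarity=volume.polarity,
        )
        for k, y, x in zip(ks, ys, xs)
    ]
    blobs.sort(key=_blob_sort_key)
    return blobs


def circle_intersection_area(r1: float, r2: float, d: float) -> float:
    """Area of the intersection of two discs with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    # lens area via the two circular segments
    a1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    a2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    return (
        r1 * r1 * (a1 - math.sin(2.0 * a1) / 2.0)
        + r2 * r2 * (a2 - math.sin(2.0 * a2) / 2.0)
    )


def disc_overlap_fraction(b1: Blob, b2: Blob) -> float:
    """Intersection area as a fraction of the smaller disc's area."""
    d = math.hypot(b1.x - b2.x, b1.y - b2.y)
    inter = circle_intersection_area(b1.radius, b2.radius, d)
    r = min(b1.radius, b2.radius)
    small = math.pi * r * r
    return inter / small if small > 0 else 0.0


def prune_overlaps(blobs: Sequence[Blob], overlap_max: float = 0.5) -> list[Blob]:
    """Greedy non-maximum suppression on a response-sorted blob list.

    Keeps the highest-response blob, then discards any later blob whose disc
    overlaps a kept disc by more than ``overlap_max`` of the smaller disc's
    area.  Input order is assumed sorted by descending response (re-sorted
    defensively with the same deterministic tie-break), so the result is
    stable and deterministic.
    """
    ordered = sorted(blobs, key=_blob_sort_key)
    kept: list[Blob] = []
    for cand in ordered:
        if all(disc_overlap_fraction(cand, k) <= overlap_max for k in kept):
            kept.append(cand)
    return kept


def detect(
    image: np.ndarray,
    schedule: SigmaSchedule | None = None,
    config: DetectionConfig | None = None,
    polarity: str = "dark",
    truncate: float = 4.0,
) -> list[Blob]:
    """End-to-end blob detection on a grayscale or RGB image.

    Composes grayscale conversion, scale-space construction, extremum
    selection and overlap pruning; deterministic for fixed inputs.  The
    default schedule, log-spaced sigma in [2, 16] with 10 scales, spans the
    nucleus sizes typical of 10x-40x cytology fields.
    """
    schedule = schedule or SigmaSchedule.logarithmic(2.0, 16.0, 10)
    config = config or DetectionConfig()
    gray = to_grayscale(image)
    volume = build_scale_space(gray, schedule, polarity=polarity, truncate=truncate)
    blobs = find_scale_space_extrema(volume, config)
    return prune_overlaps(blobs, config.overlap_max)
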
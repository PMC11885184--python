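"""Crop-window construction and cell-segment extraction.

Each detected blob of center (x, y) and radius r defines a square crop whose
ideal corners are (x - r', y - r'), (x + r', y - r'), (x - r', y + r') and
(x + r', y + r'), with r' = scale_factor * r.  The scale factor lets the
user take slightly larger windows (more cytoplasm context) or tighter ones
(nucleus only).  Windows are rasterized by flooring the min corner and
ceiling the max corner — never losing a covered pixel — then clipped to the
image; crops are taken from the ORIGINAL (color) frame even though detection
runs on grayscale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection import Blob

__all__ = ["CropBox", "Segment", "crop_box", "extract_segments"]

logger = logging.getLogger(__name__)

#: Crops whose clipped area falls below this fraction of the rasterized
#: unclipped area are dropped (uninformative slivers at frame edges).
MIN_AREA_FRACTION = 0.25


@dataclass(frozen=True)
class CropBox:
    """Axis-aligned extraction window, half-open on the max side.

    Pixels covered are rows ``y_min:y_max`` and columns ``x_min:x_max``.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    source_blob: Blob
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError("degenerate crop box")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class Segment:
    """A cropped sub-image plus the box and frame it came from."""

    pixels: np.ndarray
    box: CropBox
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != (self.box.height, self.box.width):
            raise ValueError("segment pixels do not match box extents")


def crop_box(
    blob: Blob,
    scale_factor: float,
    image_size: tuple[int, int],
    min_area_fraction: float = MIN_AREA_FRACTION,
) -> Optional[CropBox]:
    """Crop window for one blob, or ``None`` if it is dropped.

    Ideal corners are (x +/- r', y +/- r') with r' = scale_factor * radius;
    mins are floored, maxes are ceiled, then the box is clipped to
    [0, width) x [0, height).  Boxes fully outside the image, zero-area
    after clipping, or clipped below ``min_area_fraction`` of their
    rasterized unclipped area are rejected (and logged).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    height, width = image_size
    r = scale_factor * blob.radius
    # eps guards integer corner positions against float fuzz in r = sqrt(2)*sigma
    eps = 1e-9
    x_min = math.floor(blob.x - r + eps)
    x_max = math.ceil(blob.x + r - eps)
    y_min = math.floor(blob.y - r + eps)
    y_max = math.ceil(blob.y + r - eps)
    full_area = (x_max - x_min) * (y_max - y_min)

    cx_min = max(x_min, 0)
    cy_min = max(y_min, 0)
    cx_max = min(x_max, width)
    cy_max = min(y_max, height)
    if cx_min >= cx_max or cy_min >= cy_max:
        logger.warning(
            "dropping blob at (%.1f, %.1f): crop fully outside %dx%d image",
            blob.x, blob.y, width, height,
        )
        return None
    clipped_area = (cx_max - cx_min) * (cy_max - cy_min)
    if full_area > 0 and clipped_area / full_area < min_area_fraction:
        logger.warning(
            "dropping blob at (%.1f, %.1f): clipped to %.0f%% of its area",
            blob.x, blob.y, 100.0 * clipped_area / full_area,
        )
        return None
    return CropBox(
        x_min=cx_min, y_min=cy_min, x_max=cx_max, y_max=cy_max,
        source_blob=blob, scale_factor=scale_factor,
    )


def extract_segments(
    image: np.ndarray,
    blobs: Sequence[Blob],
    scale_factor: float = 1.0,
    frame_index: int = 0,
    min_area_fraction: float = MIN_AREA_FRACTION,
) -> list[Segment]:
    """One segment per surviving crop box, in blob order.

    ``image`` should be the original frame (color if available); detection
    coordinates refer to the same pixel grid either way.
    """
    arr = np.asarray(image)
    size = arr.shape[:2]
    segments: list[Segment] = []
    for blob in blobs:
        box = crop_box(blob, scale_factor, size, min_area_fraction)
        if box is None:
            continue
        pixels = arr[box.y_min : box.y_max, box.x_min : box.x_max]
        segments.append(Segment(pixels=pixels, box=box, frame_index=frame_index))
    return segments
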
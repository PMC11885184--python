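"""Gaussian scale space and the scale-normalized Laplacian-of-Gaussian (LoG) response.

The working representation is a 2D float image with intensities in [0, 1].
An image is smoothed with Gaussians of increasing standard deviation sigma,
and for each sigma the scale-normalized Laplacian

    sigma**2 * (L_xx + L_yy)

is computed, where ``L`` is the sigma-smoothed image.  The normalization by
the variance ``t = sigma**2`` makes peak responses comparable across scales,
so that a dark nucleus of characteristic scale ``sigma_b`` produces its
strongest (positive) response in the layer with sigma close to ``sigma_b``.
Stacking the layers yields the 3D scale-space volume searched for extrema by
:mod:`cytoblob.detection`.

Conventions
-----------
* sigma is always the Gaussian *standard deviation* in pixels; the variance
  ``t = sigma**2`` appears only as the normalization factor.
* Gaussian and Gaussian-derivative convolutions use analytic sampled kernels
  (via :func:`scipy.ndimage.gaussian_filter`), reflection border handling,
  and kernel truncation at ``truncate`` standard deviations (default 4).
* Dark blobs (stained nuclei on a brighter background) give *positive*
  normalized-LoG values; ``polarity="bright"`` negates the volume so the
  extremum search can always look for maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage

__all__ = [
    "REC601_WEIGHTS",
    "SigmaSchedule",
    "ScaleSpace",
    "as_float_image",
    "validate_image",
    "to_grayscale",
    "gaussian_smooth",
    "normalized_log_response",
    "build_scale_space",
]

#: Rec.601 luma weights used for RGB -> grayscale conversion.
REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])

_POLARITIES = ("dark", "bright")


def as_float_image(image: np.ndarray) -> np.ndarray:
    """Map an array to float64 intensities in [0, 1].

    Integer arrays are rescaled linearly from the full range of their dtype
    (uint8 -> /255, uint16 -> /65535, ...).  Float arrays must already lie in
    [0, 1].  Raises ``ValueError`` for non-finite values or out-of-range
    floats.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = (arr.astype(np.float64) - info.min) / (info.max - info.min)
    elif np.issubdtype(arr.dtype, np.bool_):
        arr = arr.astype(np.float64)
    else:
        arr = arr.astype(np.float64)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError(
                "float image intensities must lie in [0, 1]; "
                f"got range [{arr.min():g}, {arr.max():g}]"
            )
        arr = np.clip(arr, 0.0, 1.0)
    return arr


def validate_image(image: np.ndarray) -> np.ndarray:
    """Validate and return a 2D intensity image in [0, 1].

    Requires height >= 3 and width >= 3 (the extremum search needs interior
    pixels).
    """
    arr = as_float_image(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3 pixels, got {arr.shape}")
    return arr


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to a single-channel intensity image.

    Uses Rec.601 luma weights (0.299, 0.587, 0.114).  Already-grayscale
    input (2D, or a trailing singleton channel) passes through unchanged.
    Integer input is first rescaled to [0, 1].
    """
    arr = as_float_image(image)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ REC601_WEIGHTS
    if arr.ndim == 3 and arr.shape[2] == 4:  # RGBA: alpha ignored
        return arr[:, :, :3] @ REC601_WEIGHTS
    raise ValueError(
        f"expected 1, 3 or 4 channels, got array of shape {arr.shape}"
    )


@dataclass(frozen=True)
class SigmaSchedule:
    """Ordered set of Gaussian standard deviations defining the scale axis.

    Parameters
    ----------
    sigmas
        Strictly increasing positive standard deviations, in pixels.
        At least 3 values are required: scale-space extrema need a scale
        neighbor on both sides, so only interior scales can fire.
    spacing
        ``"linear"`` or ``"logarithmic"``; informational (the values in
        ``sigmas`` are authoritative).
    """

    sigmas: tuple[float, ...]
    spacing: str = "logarithmic"

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigmas)
        object.__setattr__(self, "sigmas", sig)
        if len(sig) < 3:
            raise ValueError("a sigma schedule needs at least 3 scales")
        if any(s <= 0 for s in sig):
            raise ValueError("all sigmas must be positive")
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigmas must be strictly increasing")
        if self.spacing not in ("linear", "logarithmic"):
            raise ValueError(f"unknown spacing {self.spacing!r}")

    @classmethod
    def linear(cls, sigma_min: float, sigma_max: float, n: int) -> "SigmaSchedule":
        return cls(tuple(np.linspace(sigma_min, sigma_max, n)), spacing="linear")

    @classmethod
    def logarithmic(cls, sigma_min: float, sigma_max: float, n: int) -> "SigmaSchedule":
        return cls(
            tuple(np.geomspace(sigma_min, sigma_max, n)), spacing="logarithmic"
        )

    def scaled(self, factor: float) -> "SigmaSchedule":
        """Schedule with every sigma multiplied by ``factor``."""
        return SigmaSchedule(tuple(s * factor for s in self.sigmas), self.spacing)

    def nearest_index(self, sigma: float) -> int:
        """Index of the schedule value closest to ``sigma``."""
        return int(np.argmin(np.abs(np.asarray(self.sigmas) - sigma)))

    def __iter__(self) -> Iterator[float]:
        return iter(self.sigmas)

    def __len__(self) -> int:
        return len(self.sigmas)

    def __getitem__(self, i: int) -> float:
        return self.sigmas[i]


@dataclass
class ScaleSpace:
    """Stack of scale-normalized LoG response maps.

    ``responses[k]`` is the layer for ``schedule.sigmas[k]``, same height and
    width as the source image.  With ``polarity="dark"`` the raw normalized
    Laplacian is stored (dark blobs -> positive peaks); ``"bright"`` stores
    its negation, so maxima always mark blobs of the requested polarity.
    """

    responses: np.ndarray  # (n_scales, height, width)
    schedule: SigmaSchedule
    polarity: str = "dark"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 3:
            raise ValueError("responses must be a (scale, y, x) volume")
        if self.responses.shape[0] != len(self.schedule):
            raise ValueError(
                f"{self.responses.shape[0]} layers for "
                f"{len(self.schedule)} scheduled sigmas"
            )
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")

    @property
    def sigmas(self) -> tuple[float, ...]:
        return self.schedule.sigmas

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.responses.shape


def gaussian_smooth(
    image: np.ndarray, sigma: float, truncate: float = 4.0
) -> np.ndarray:
    """Convolve ``image`` with a normalized 2D Gaussian of std ``sigma``.

    The kernel is the sampled analytic Gaussian
    ``g(x, y) = exp(-(x^2 + y^2) / (2 sigma^2)) / (2 pi sigma^2)``,
    truncated at ``truncate`` standard deviations and renormalized; borders
    are handled by reflection, which conserves the image mean.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    arr = validate_image(image)
    return ndimage.gaussian_filter(arr, sigma, mode="reflect", truncate=truncate)


def normalized_log_response(
    image: np.ndarray, sigma: float, truncate: float = 4.0
) -> np.ndarray:
    """Scale-normalized Laplacian of the sigma-smoothed image.

    Returns ``sigma**2 * (L_xx + L_yy)`` where second derivatives are taken
    by convolution with analytic Gaussian second-derivative kernels.  A dark
    region of characteristic scale ~sigma yields a positive response.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    arr = validate_image(image)
    g0, g2 = _gaussian_derivative_kernels(sigma, truncate)
    lyy = ndimage.correlate1d(
        ndimage.correlate1d(arr, g2, axis=0, mode="reflect"),
        g0, axis=1, mode="reflect",
    )
    lxx = ndimage.correlate1d(
        ndimage.correlate1d(arr, g0, axis=0, mode="reflect"),
        g2, axis=1, mode="reflect",
    )
    return (sigma * sigma) * (lxx + lyy)


def _gaussian_derivative_kernels(
    sigma: float, truncate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled 1D Gaussian and Gaussian-second-derivative kernels.

    Both share the smoothing kernel's normalization.  The derivative kernel
    is de-meaned so its weights sum exactly to zero: truncation leaves a
    small DC residual that would otherwise break the exact annihilation of
    constant images.
    """
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-(x * x) / (2.0 * sigma * sigma))
    norm = phi.sum()
    g0 = phi / norm
    g2 = ((x * x - sigma * sigma) / sigma**4) * phi / norm
    g2 -= g2.mean()
    return g0, g2


def build_scale_space(
    image: np.ndarray,
    schedule: SigmaSchedule,
    polarity: str = "dark",
    truncate: float = 4.0,
) -> ScaleSpace:
    """Build the normalized-LoG volume, one layer per scheduled sigma.

    ``polarity="bright"`` flips the sign of every layer, so the extremum
    search in :mod:`cytoblob.detection` always looks for maxima.
    """
    if polarity not in _POLARITIES:
        raise ValueError(f"polarity must be one of {_POLARITIES}")
    arr = validate_image(image)
    layers = np.stack(
        [normalized_log_response(arr, s, truncate=truncate) for s in schedule]
    )
    if polarity == "bright":
        layers = -layers
    return ScaleSpace(responses=layers, schedule=schedule, polarity=polarity)
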
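"""Vesicle-matched difference-of-Gaussians filtering and binarization.

The detector is the difference of two discretized 2D Gaussians: a narrow one
(σ = 150 nm by default) matched to a near-diffraction-limited spot, minus a
wide one (σ = 300 nm) that estimates the local diffuse background.  Each
Gaussian is renormalized *after truncation* to sum to exactly 1 on the pixel
grid, so the kernel sums to zero and a spatially flat image — whatever its
level — filters to (numerically) nothing.  Filtered images are binarized by
a single global threshold per image; because the original thresholds were
chosen by eye and are unrecoverable, a deterministic automatic rule
(Otsu's criterion over the strictly positive filtered values) is the
default, with the chosen value always recorded on the mask.

Sigmas are specified in nanometres and converted to pixels through the
image calibration; filtering is strictly 2D, applied per plane or slab.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ParameterError, ValidationError

__all__ = [
    "DOGParams",
    "BinaryMask",
    "build_dog_kernel",
    "dog_filter",
    "global_threshold",
    "auto_threshold",
]


@dataclass(frozen=True)
class DOGParams:
    """Physical parameters of the difference-of-Gaussians detector.

    ``sigma_small_nm`` is the spot-matched scale, ``sigma_large_nm`` the
    background-estimation scale; the kernel is truncated at
    ``truncation_radius_sigmas × sigma_large_nm`` from its center.
    """

    sigma_small_nm: float = 150.0
    sigma_large_nm: float = 300.0
    truncation_radius_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_small_nm <= 0 or self.sigma_large_nm <= 0:
            raise ParameterError("sigmas must be positive")
        if self.truncation_radius_sigmas <= 0:
            raise ParameterError("truncation_radius_sigmas must be positive")
        if self.sigma_small_nm >= self.sigma_large_nm:
            raise ParameterError(
                "sigma_small_nm must be < sigma_large_nm for a band-pass "
                f"(got {self.sigma_small_nm} >= {self.sigma_large_nm})"
            )


@dataclass
class BinaryMask:
    """Per-channel detection map with full thresholding provenance.

    ``values`` is a {0,1} uint8 array, either ``(y, x)`` or ``(slab, y, x)``.
    ``threshold_used`` is the global threshold that produced it.
    """

    values: np.ndarray
    label: str = ""
    threshold_used: float = float("nan")
    time_min: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)

    @property
    def n_on(self) -> int:
        return int(self.values.sum())

    @property
    def on_fraction(self) -> float:
        return self.n_on / self.values.size


def _discrete_gaussian(sigma_px: float, radius_px: int) -> np.ndarray:
    """Truncated 2D Gaussian on an odd grid, renormalized to unit sum."""
    coords = np.arange(-radius_px, radius_px + 1, dtype=float)
    g1 = np.exp(-0.5 * (coords / sigma_px) ** 2)
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def build_dog_kernel(params: DOGParams, pixel_size_nm: float) -> np.ndarray:
    """Build the zero-sum DoG kernel for a given lateral calibration.

    The kernel is ``G_small − G_large`` where both truncated Gaussians share
    one support (radius ``truncation_radius_sigmas × σ_large``, in pixels)
    and each sums to exactly 1, so the difference sums to 0 to machine
    precision.
    """
    if pixel_size_nm <= 0:
        raise ParameterError(f"pixel_size_nm must be > 0, got {pixel_size_nm}")
    sigma_small_px = params.sigma_small_nm / pixel_size_nm
    sigma_large_px = params.sigma_large_nm / pixel_size_nm
    radius = int(np.ceil(params.truncation_radius_sigmas * sigma_large_px))
    radius = max(radius, 1)
    return (
        _discrete_gaussian(sigma_small_px, radius)
        - _discrete_gaussian(sigma_large_px, radius)
    )


def dog_filter(
    plane: np.ndarray, params: DOGParams, pixel_size_nm: float
) -> np.ndarray:
    """Convolve one 2D plane with the DoG kernel (reflect boundary).

    Returns a same-shape real-valued image: positive at spot-scale structure,
    near zero over flat or smoothly varying background.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValidationError(f"dog_filter expects a 2D plane, got ndim={plane.ndim}")
    if not np.all(np.isfinite(plane)):
        raise ValidationError("plane contains non-finite values")
    kernel = build_dog_kernel(params, pixel_size_nm)
    pad = kernel.shape[0] // 2
    padded = np.pad(plane, pad, mode="reflect")
    out = oaconvolve(padded, kernel, mode="same")
    return out[pad:-pad, pad:-pad]


def global_threshold(
    filtered: np.ndarray,
    threshold: float,
    label: str = "",
    time_min: float = 0.0,
) -> BinaryMask:
    """Binarize a filtered image: 1 where value > threshold, else 0."""
    filtered = np.asarray(filtered, dtype=float)
    if not np.isfinite(threshold):
        raise ParameterError(f"threshold must be finite, got {threshold}")
    return BinaryMask(
        values=(filtered > threshold).astype(np.uint8),
        label=label,
        threshold_used=float(threshold),
        time_min=time_min,
    )


def auto_threshold(
    filtered: np.ndarray, method: str = "otsu-positive", q: float | None = None
) -> float:
    """Choose a global threshold for a DoG-filtered image.

    ``"otsu-positive"`` applies Otsu's between-class criterion to the
    strictly positive filtered values only — the negative lobe of the DoG
    response carries no object evidence and would otherwise dominate the
    histogram.  ``"quantile"`` returns the ``q``-th quantile of all values.
    """
    filtered = np.asarray(filtered, dtype=float)
    if method == "otsu-positive":
        positive = filtered[filtered > 0]
        if positive.size == 0:
            raise DegenerateInputError(
                "no positive filtered values; cannot auto-threshold"
            )
        if positive.size == 1 or np.ptp(positive) == 0:
            # a single response level: threshold just below it keeps it
            return float(positive.min()) * 0.5
        return float(threshold_otsu(positive))
    if method == "quantile":
        if q is None or not 0.0 <= q <= 1.0:
            raise ParameterError(f"quantile method needs q in [0, 1], got {q}")
        return float(np.quantile(filtered, q))
    raise ParameterError(f"unknown threshold method {method!r}")
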
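"""Confocal-style intensity readouts: totals and perinuclear line profiles.

Two measurements accompany the co-localization pipeline.  ``total_intensity``
sums a channel over the whole image or a region mask (uptake over time).
``perinuclear_readout`` samples the image along a user-drawn line that
crosses the nucleus, finds where the line enters and leaves the nucleus
mask, and reads the intensity 10 pixels beyond each crossing — a perinuclear
accumulation measure that is robust to the nucleus itself being dye-free.
Line endpoints are explicit inputs (they were drawn by hand in the original
workflow); nothing here auto-selects them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import AnnotationError, DegenerateInputError, GeometryError
from .image_io import ImageStack
from .vesicle_filter import BinaryMask

__all__ = ["LineProfile", "total_intensity", "perinuclear_readout"]

FLANK_OFFSET_PX = 10.0  # distance beyond each nucleus crossing, along the line


@dataclass
class LineProfile:
    """A sampled line through a cell with its perinuclear flank readout.

    ``samples`` is ``(position_px, intensity)`` at unit-pixel steps from the
    first endpoint; ``nucleus_interval`` is the (entry, exit) positions where
    the line crosses the nucleus mask; ``flank_values`` are the intensities
    exactly 10 px outside each crossing (left = before entry, right = after
    exit, in sample order).
    """

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    samples: np.ndarray  # (n, 2): position, intensity
    nucleus_interval: tuple[float, float]
    flank_values: tuple[float, float]

    @property
    def mean_flank(self) -> float:
        return float(np.mean(self.flank_values))


def total_intensity(
    stack: ImageStack, channel: str, region: BinaryMask | None = None
) -> float:
    """Sum of a channel's intensities over a region (whole image if None)."""
    volume = stack.channel(channel)
    if region is None:
        return float(volume.sum())
    mask = region.values
    if mask.shape != volume.shape and mask.shape != volume.shape[1:]:
        raise GeometryError(
            f"region shape {mask.shape} does not match channel shape {volume.shape}"
        )
    if mask.sum() == 0:
        raise DegenerateInputError("region mask is empty")
    return float((volume * mask).sum())


def _sample_line(
    plane: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    order: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions (px), (y, x) coordinates and interpolated values at 1 px steps."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise GeometryError("line endpoints coincide")
    positions = np.arange(0.0, np.floor(length) + 1.0)
    unit = (p1 - p0) / length
    coords = p0[:, None] + unit[:, None] * positions[None, :]
    values = map_coordinates(plane.astype(float), coords, order=order, mode="nearest")
    return positions, coords, values


def perinuclear_readout(
    plane: np.ndarray,
    nucleus_mask: BinaryMask,
    endpoints: tuple[tuple[float, float], tuple[float, float]],
    interpolation: str = "bilinear",
) -> LineProfile:
    """Sample a line through the cell and read flanks 10 px outside the nucleus.

    Parameters
    ----------
    plane
        2D intensity image of the measured channel.
    nucleus_mask
        Binary nucleus (DAPI-derived) mask, same shape as *plane*.
    endpoints
        Two ``(y, x)`` points in pixel coordinates; the segment must cross
        the nucleus in one contiguous interval and leave at least 10 px of
        in-image line on both sides.
    interpolation
        ``"bilinear"`` (default) or ``"nearest"`` for exact-integer fixtures.

    Raises
    ------
    GeometryError
        If the line misses the nucleus, the nucleus interval touches the
        line's ends, or a flank point falls outside the image.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise GeometryError(f"expected 2D plane, got ndim={plane.ndim}")
    if nucleus_mask.values.shape != plane.shape:
        raise GeometryError("nucleus mask shape does not match plane")
    if interpolation not in ("bilinear", "nearest"):
        raise AnnotationError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "bilinear" else 0

    positions, coords, values = _sample_line(plane, endpoints[0], endpoints[1], order)
    inside = map_coordinates(
        nucleus_mask.values.astype(float), coords, order=0, mode="constant"
    ) > 0.5

    if not inside.any():
        raise GeometryError("line does not intersect the nucleus mask")
    idx = np.flatnonzero(inside)
    if not np.all(np.diff(idx) == 1):
        raise GeometryError("line crosses the nucleus in more than one interval")
    if idx[0] == 0 or idx[-1] == len(positions) - 1:
        raise GeometryError("nucleus interval reaches the end of the line")

    entry, exit_ = positions[idx[0]], positions[idx[-1]]
    flank_positions = (entry - FLANK_OFFSET_PX, exit_ + FLANK_OFFSET_PX)
    if flank_positions[0] < 0 or flank_positions[1] > positions[-1]:
        raise GeometryError(
            "flank point 10 px beyond the nucleus falls outside the sampled line"
        )

    p0 = np.asarray(endpoints[0], dtype=float)
    unit = (np.asarray(endpoints[1], dtype=float) - p0) / float(
        np.hypot(*(np.asarray(endpoints[1], dtype=float) - p0))
    )
    flank_coords = p0[:, None] + unit[:, None] * np.asarray(flank_positions)[None, :]
    if (
        (flank_coords < -0.5).any()
        or (flank_coords[0] > plane.shape[0] - 0.5).any()
        or (flank_coords[1] > plane.shape[1] - 0.5).any()
    ):
        raise GeometryError("flank point falls outside the image")
    flank_values = map_coordinates(plane, flank_coords, order=order, mode="nearest")

    return LineProfile(
        endpoints=(tuple(endpoints[0]), tuple(endpoints[1])),
        samples=np.column_stack([positions, values]),
        nucleus_interval=(float(entry), float(exit_)),
        flank_values=(float(flank_values[0]), float(flank_values[1])),
    )
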
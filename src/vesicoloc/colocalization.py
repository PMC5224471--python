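"""Pixel-overlap co-localization on binary detection masks.

The headline statistic is the percent co-localization of "B with A":

    100 × Σ_x Σ_y [A(x, y, t) · B(x, y, t)] / Σ_x Σ_y B(x, y, t)

where A and B are the binary detection masks of the two labels — i.e. the
fraction of B's detected pixels that also carry A.  The normalization is
asymmetric; both directions are computed and the direction is always stated.

Chance overlap is estimated by a rotation null: one mask is rotated 180°
in-plane (index reversal on both axes, exact for any grid parity) and the
same equation is re-evaluated.  For independently positioned signals this
measures the overlap expected from mask density alone.

For z-stacks, analysis runs on thicker optical slabs (500 nm by default):
consecutive z slices are max-projected into slabs, each slab is filtered,
thresholded and binarized in 2D, and pixel counts are *pooled* across slabs
before forming the whole-cell ratio — slabs with more detected signal weigh
more, and empty slabs contribute nothing rather than an undefined ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, GeometryError, ParameterError
from .image_io import ImageStack
from .vesicle_filter import (
    BinaryMask,
    DOGParams,
    auto_threshold,
    dog_filter,
    global_threshold,
)

__all__ = [
    "ColocResult",
    "Slab",
    "ThresholdConfig",
    "coloc_percent",
    "coloc_threeway",
    "rotate_180",
    "rotation_null",
    "slab_project",
    "cell_coloc",
]


@dataclass
class ColocResult:
    """Co-localization of one label pair (optionally a triple) for one cell.

    ``percent`` is ``None`` (undefined) when the normalizing mask is empty;
    an empty channel must never masquerade as "0% co-localization".
    ``per_slab`` records (slab index, numerator, denominator) pixel counts.
    """

    label_A: str
    label_B: str
    direction: str  # "B_with_A" (denominator = Σ B) or "A_with_B"
    numerator_px: int
    denominator_px: int
    label_C: str | None = None
    null_percent: float | None = None
    null_defined: bool = True
    per_slab: list[tuple[int, int, int]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    partial_slab: bool = False
    time_min: float = 0.0
    cell_id: str = ""
    condition: str = ""

    @property
    def percent(self) -> float | None:
        if self.denominator_px == 0:
            return None
        return 100.0 * self.numerator_px / self.denominator_px

    @property
    def defined(self) -> bool:
        return self.denominator_px > 0


def _check_shapes(*masks: BinaryMask) -> None:
    shapes = {m.values.shape for m in masks}
    if len(shapes) != 1:
        raise GeometryError(f"mask shapes differ: {sorted(shapes)}")


def _direction_counts(
    a: np.ndarray, b: np.ndarray, direction: str
) -> tuple[int, int]:
    overlap = int(np.sum(a * b))
    if direction == "B_with_A":
        return overlap, int(b.sum())
    if direction == "A_with_B":
        return overlap, int(a.sum())
    raise ParameterError(f"direction must be 'B_with_A' or 'A_with_B', got {direction!r}")


def coloc_percent(
    mask_A: BinaryMask, mask_B: BinaryMask, direction: str = "B_with_A"
) -> ColocResult:
    """Percent co-localization of one mask pair per the overlap equation.

    ``direction="B_with_A"`` normalizes by Σ B (what fraction of B's pixels
    carry A); ``"A_with_B"`` normalizes by Σ A.
    """
    _check_shapes(mask_A, mask_B)
    num, den = _direction_counts(mask_A.values, mask_B.values, direction)
    return ColocResult(
        label_A=mask_A.label,
        label_B=mask_B.label,
        direction=direction,
        numerator_px=num,
        denominator_px=den,
        thresholds={
            mask_A.label: mask_A.threshold_used,
            mask_B.label: mask_B.threshold_used,
        },
        time_min=mask_B.time_min,
    )


def coloc_threeway(
    mask_A: BinaryMask,
    mask_B: BinaryMask,
    mask_C: BinaryMask,
    normalizer: str,
) -> ColocResult:
    """Three-way overlap percent, normalized by the named label's mask."""
    _check_shapes(mask_A, mask_B, mask_C)
    by_label = {m.label: m for m in (mask_A, mask_B, mask_C)}
    if normalizer not in by_label:
        raise ParameterError(
            f"normalizer {normalizer!r} not among labels {sorted(by_label)}"
        )
    triple = mask_A.values * mask_B.values * mask_C.values
    return ColocResult(
        label_A=mask_A.label,
        label_B=mask_B.label,
        label_C=mask_C.label,
        direction=f"triple_with_{normalizer}",
        numerator_px=int(triple.sum()),
        denominator_px=int(by_label[normalizer].values.sum()),
        thresholds={m.label: m.threshold_used for m in (mask_A, mask_B, mask_C)},
        time_min=mask_B.time_min,
    )


def rotate_180(mask: BinaryMask) -> BinaryMask:
    """Rotate a mask 180° in-plane: reverse both spatial axes.

    Exact for even and odd dimensions; for ``(slab, y, x)`` input the slab
    axis is left untouched.
    """
    return BinaryMask(
        values=mask.values[..., ::-1, ::-1].copy(),
        label=mask.label,
        threshold_used=mask.threshold_used,
        time_min=mask.time_min,
    )


def rotation_null(
    mask_A: BinaryMask,
    mask_B: BinaryMask,
    rotate: str = "B",
    direction: str = "B_with_A",
) -> ColocResult:
    """Chance-overlap control: rotate one mask 180°, recompute the percent.

    The result of :func:`coloc_percent` on the rotated pair is stored in
    ``null_percent`` (the plain percent fields also hold the rotated counts).
    """
    _check_shapes(mask_A, mask_B)
    if rotate not in ("A", "B"):
        raise ParameterError(f"rotate must be 'A' or 'B', got {rotate!r}")
    if rotate == "A":
        result = coloc_percent(rotate_180(mask_A), mask_B, direction)
    else:
        result = coloc_percent(mask_A, rotate_180(mask_B), direction)
    result.null_percent = result.percent
    result.null_defined = result.defined
    return result


@dataclass
class Slab:
    """One projected optical slab: 2D plane plus bookkeeping."""

    index: int
    plane: np.ndarray
    n_slices: int
    partial: bool = False


def slab_project(
    stack: ImageStack, channel: str, slab_nm: float = 500.0
) -> list[Slab]:
    """Max-project consecutive z slices of one channel into optical slabs.

    ``round(slab_nm / z_spacing_nm)`` slices form one slab; a trailing
    incomplete group is kept and flagged ``partial``.  Raises for 2D input —
    a single plane needs no projection and should be analyzed directly.
    """
    if stack.z_spacing_nm is None or stack.n_z == 1:
        raise GeometryError(
            "stack is 2D (single plane / no z spacing); use the plane directly"
        )
    if slab_nm < stack.z_spacing_nm:
        raise ParameterError(
            f"slab_nm ({slab_nm}) must be >= z_spacing_nm ({stack.z_spacing_nm})"
        )
    per_slab = int(round(slab_nm / stack.z_spacing_nm))
    volume = stack.channel(channel)
    slabs: list[Slab] = []
    for i, start in enumerate(range(0, volume.shape[0], per_slab)):
        group = volume[start : start + per_slab]
        slabs.append(
            Slab(
                index=i,
                plane=group.max(axis=0),
                n_slices=group.shape[0],
                partial=group.shape[0] < per_slab,
            )
        )
    return slabs


@dataclass(frozen=True)
class ThresholdConfig:
    """How to binarize filtered images.

    ``method`` is "otsu-positive" or "quantile" (with ``quantile_q``);
    ``values`` fixes the threshold per channel label, bypassing the
    automatic rule for that channel.
    """

    method: str = "otsu-positive"
    quantile_q: float | None = None
    values: Mapping[str, float] = field(default_factory=dict)

    def threshold_for(self, filtered: np.ndarray, label: str) -> float:
        if label in self.values:
            return float(self.values[label])
        return auto_threshold(filtered, self.method, self.quantile_q)


def _channel_slabs(stack: ImageStack, label: str, slab_nm: float) -> list[Slab]:
    if stack.z_spacing_nm is None or stack.n_z == 1:
        return [Slab(index=0, plane=stack.channel(label)[0], n_slices=1)]
    return slab_project(stack, label, slab_nm)


def _binarize_slabs(
    slabs: Sequence[Slab],
    label: str,
    params: DOGParams,
    pixel_size_nm: float,
    thresholds: ThresholdConfig,
    time_min: float,
    threshold_scope: str = "stack",
) -> tuple[list[BinaryMask], list[float]]:
    """Filter each slab and binarize with one global or per-slab threshold.

    ``threshold_scope="stack"`` (the default) pools the filtered values of
    every slab and chooses a single threshold for the whole channel — the
    global-threshold reading, and the one that keeps slabs devoid of signal
    from being thresholded inside pure noise.  ``"slab"`` re-thresholds each
    slab independently.
    """
    filtered_slabs = [dog_filter(s.plane, params, pixel_size_nm) for s in slabs]
    if threshold_scope not in ("stack", "slab"):
        raise ParameterError(f"threshold_scope must be 'stack' or 'slab'")

    def choose(arr: np.ndarray) -> float:
        try:
            return thresholds.threshold_for(arr, label)
        except DegenerateInputError:
            # no positive response anywhere: detect nothing
            return float(np.max(arr)) if arr.size else 0.0

    if threshold_scope == "stack":
        per_slab_thr = [choose(np.stack(filtered_slabs))] * len(slabs)
    else:
        per_slab_thr = [choose(f) for f in filtered_slabs]
    masks = [
        global_threshold(f, thr, label=label, time_min=time_min)
        for f, thr in zip(filtered_slabs, per_slab_thr)
    ]
    return masks, per_slab_thr


def cell_coloc(
    stack: ImageStack,
    label_A: str,
    label_B: str,
    params: DOGParams | None = None,
    thresholds: ThresholdConfig | None = None,
    slab_nm: float = 500.0,
    direction: str = "B_with_A",
    rotate: str = "B",
    threshold_scope: str = "stack",
) -> ColocResult:
    """Whole-cell co-localization: slab → filter → threshold → pooled overlap.

    Each channel is slab-projected, DoG-filtered and binarized per slab;
    numerator and denominator pixel counts are accumulated over slabs and
    the whole-cell percent is the pooled ratio (not a mean of slab ratios).
    The 180°-rotation null is pooled the same way and stored alongside.
    """
    params = params or DOGParams()
    thresholds = thresholds or ThresholdConfig()
    slabs_A = _channel_slabs(stack, label_A, slab_nm)
    slabs_B = _channel_slabs(stack, label_B, slab_nm)
    masks_A, thr_A = _binarize_slabs(
        slabs_A, label_A, params, stack.pixel_size_nm, thresholds,
        stack.time_min, threshold_scope,
    )
    masks_B, thr_B = _binarize_slabs(
        slabs_B, label_B, params, stack.pixel_size_nm, thresholds,
        stack.time_min, threshold_scope,
    )

    num = den = null_num = null_den = 0
    per_slab: list[tuple[int, int, int]] = []
    for slab, mA, mB in zip(slabs_A, masks_A, masks_B):
        n, d = _direction_counts(mA.values, mB.values, direction)
        num += n
        den += d
        per_slab.append((slab.index, n, d))
        rotated = rotation_null(mA, mB, rotate=rotate, direction=direction)
        null_num += rotated.numerator_px
        null_den += rotated.denominator_px

    null_percent = 100.0 * null_num / null_den if null_den > 0 else None
    return ColocResult(
        label_A=label_A,
        label_B=label_B,
        direction=direction,
        numerator_px=num,
        denominator_px=den,
        null_percent=null_percent,
        null_defined=null_den > 0,
        per_slab=per_slab,
        # per-channel provenance: the median across slab thresholds
        thresholds={
            label_A: float(np.median(thr_A)),
            label_B: float(np.median(thr_B)),
        },
        partial_slab=any(s.partial for s in slabs_A + slabs_B),
        time_min=stack.time_min,
        cell_id=stack.cell_id,
        condition=stack.condition,
    )
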
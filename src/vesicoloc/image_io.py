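"""Calibrated multi-channel image stacks and their (OME-)TIFF round trip.

The canonical in-memory layout is a ``(channel, z, y, x)`` array: 2D images
are carried with a singleton z so every downstream operation sees one axis
order.  Physical calibration (lateral pixel size, z spacing, both in nm) is
mandatory — the pipeline's detection filter is parameterised in nanometres,
so an uncalibrated image is unusable and loading one without an explicit
override is an error, never a silent default.

Acquisition annotations (time point in minutes, condition label, cell ID)
have no standard TIFF slot; they are attached from a sidecar CSV keyed by
file name, or passed as overrides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import AnnotationError, CalibrationError, ValidationError

__all__ = ["ImageStack", "load_stack", "save_stack", "read_annotations"]

_NM_PER_UM = 1000.0


@dataclass
class ImageStack:
    """A calibrated multi-channel intensity volume.

    Parameters
    ----------
    intensities
        Non-negative, finite array indexed ``(channel, z, y, x)``.  2D data
        must be supplied with a singleton z axis.
    pixel_size_nm
        Lateral pixel size in nm/pixel (x and y assumed equal).
    z_spacing_nm
        Spacing between z slices in nm; ``None`` for single-plane data.
    channel_labels
        One short unique label per channel, e.g. ``"sd-rxRNA-Cy3"``.
    time_min, condition, cell_id
        Acquisition annotations; default to a zero time point and empty
        strings when unknown.
    """

    intensities: np.ndarray
    pixel_size_nm: float
    channel_labels: Sequence[str]
    z_spacing_nm: float | None = None
    time_min: float = 0.0
    condition: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise ValidationError(
                f"intensities must be (channel, z, y, x); got ndim={arr.ndim}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("intensities contain non-finite values")
        if np.any(arr < 0):
            raise ValidationError("intensities contain negative values")
        self.intensities = arr
        labels = list(self.channel_labels)
        if len(labels) != arr.shape[0]:
            raise AnnotationError(
                f"{len(labels)} channel labels for {arr.shape[0]} channels"
            )
        if len(set(labels)) != len(labels):
            raise AnnotationError(f"channel labels not unique: {labels}")
        self.channel_labels = labels
        if not (self.pixel_size_nm is not None and self.pixel_size_nm > 0):
            raise CalibrationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.z_spacing_nm is not None and not self.z_spacing_nm > 0:
            raise CalibrationError(f"z_spacing_nm must be > 0, got {self.z_spacing_nm}")
        if self.time_min < 0:
            raise AnnotationError(f"time_min must be >= 0, got {self.time_min}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_z(self) -> int:
        return self.intensities.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for one channel label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise AnnotationError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.intensities[idx]

    def replace(self, **changes: Any) -> "ImageStack":
        return dataclasses.replace(self, **changes)


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write *stack* to an OME-TIFF with calibration in the OME pixel fields.

    Channel labels are stored as OME channel names; intensities round-trip
    bit-exactly for integer dtypes.  Time/condition/cell annotations are not
    part of the file (use a sidecar table; see :func:`read_annotations`).
    """
    path = Path(path)
    px_um = stack.pixel_size_nm / _NM_PER_UM
    metadata: dict[str, Any] = {
        "axes": "CZYX",
        "PhysicalSizeX": px_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": px_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(stack.channel_labels)},
    }
    if stack.z_spacing_nm is not None:
        metadata["PhysicalSizeZ"] = stack.z_spacing_nm / _NM_PER_UM
        metadata["PhysicalSizeZUnit"] = "µm"
    try:
        tifffile.imwrite(path, stack.intensities, ome=True, metadata=metadata)
    except OSError as exc:
        raise OSError(f"cannot write stack to {path}: {exc}") from exc
    return path


def _ome_calibration(tf: tifffile.TiffFile) -> dict[str, Any]:
    """Pull pixel sizes (nm) and channel names out of OME-XML, if present."""
    out: dict[str, Any] = {}
    if not tf.is_ome or tf.ome_metadata is None:
        return out
    meta = tifffile.xml2dict(tf.ome_metadata)
    image = meta.get("OME", {}).get("Image", {})
    if isinstance(image, list):
        image = image[0]
    pixels = image.get("Pixels", {})
    unit_scale = {"µm": 1000.0, "um": 1000.0, "nm": 1.0, "mm": 1e6}

    def physical(axis: str) -> float | None:
        value = pixels.get(f"PhysicalSize{axis}")
        if value is None:
            return None
        unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
        return float(value) * unit_scale.get(unit, 1000.0)

    px = physical("X")
    if px is not None:
        out["pixel_size_nm"] = px
    pz = physical("Z")
    if pz is not None:
        out["z_spacing_nm"] = pz
    channels = pixels.get("Channel")
    if channels is not None:
        if isinstance(channels, Mapping):
            channels = [channels]
        names = [c.get("Name") for c in channels]
        if all(n is not None for n in names):
            out["channel_labels"] = [str(n) for n in names]
    return out


def load_stack(path: str | Path, overrides: Mapping[str, Any] | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Calibration and channel names are taken from OME metadata when present;
    OME pixel-size fields win over plain TIFF resolution tags.  Any key in
    *overrides* (``pixel_size_nm``, ``z_spacing_nm``, ``channel_labels``,
    ``time_min``, ``condition``, ``cell_id``) replaces the file value.

    Raises
    ------
    CalibrationError
        If no lateral pixel size is available from metadata or overrides.
    AnnotationError
        If channel labels disagree with the channel count.
    """
    path = Path(path)
    overrides = dict(overrides or {})
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes
        meta = _ome_calibration(tf)

    arr = _canonical_czyx(arr, axes)

    fields: dict[str, Any] = {}
    for key in ("pixel_size_nm", "z_spacing_nm", "channel_labels"):
        if key in overrides:
            fields[key] = overrides.pop(key)
        elif key in meta:
            fields[key] = meta[key]
    for key in ("time_min", "condition", "cell_id"):
        if key in overrides:
            fields[key] = overrides.pop(key)
    if overrides:
        raise AnnotationError(f"unknown override keys: {sorted(overrides)}")

    if "pixel_size_nm" not in fields:
        raise CalibrationError(
            f"{path.name}: no lateral pixel size in metadata and no override given"
        )
    if "channel_labels" not in fields:
        fields["channel_labels"] = [f"ch{i}" for i in range(arr.shape[0])]
    return ImageStack(intensities=arr, **fields)


def _canonical_czyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series into (channel, z, y, x), padding singletons."""
    axes = axes.upper().replace("S", "C")  # samples treated as channels
    if arr.ndim == 2:
        axes = "YX"
    order = [ax for ax in axes if ax in "CZYX"]
    if len(order) != arr.ndim or len(set(order)) != len(order):
        raise ValidationError(f"unsupported TIFF axis layout {axes!r}")
    # transpose present axes into CZYX relative order, then pad missing ones
    arr = np.transpose(arr, [order.index(a) for a in "CZYX" if a in order])
    for position, ax in enumerate("CZYX"):
        if ax not in order:
            arr = np.expand_dims(arr, position)
    return arr


def read_annotations(csv_path: str | Path) -> pd.DataFrame:
    """Read a sidecar annotation table.

    Expected columns: ``file`` plus any of ``channel_labels`` (``;``-separated),
    ``time_min``, ``condition``, ``cell_id``, ``pixel_size_nm``,
    ``z_spacing_nm``.  Returns a DataFrame indexed by file name whose rows can
    be fed to :func:`load_stack` as overrides via :func:`annotation_overrides`.
    """
    df = pd.read_csv(csv_path)
    if "file" not in df.columns:
        raise AnnotationError(f"{csv_path}: annotation table needs a 'file' column")
    return df.set_index("file")


def annotation_overrides(row: pd.Series) -> dict[str, Any]:
    """Convert one annotation row into a load_stack overrides dict."""
    out: dict[str, Any] = {}
    for key in ("time_min", "pixel_size_nm", "z_spacing_nm"):
        if key in row.index and pd.notna(row[key]):
            out[key] = float(row[key])
    for key in ("condition", "cell_id"):
        if key in row.index and pd.notna(row[key]):
            out[key] = str(row[key])
    if "channel_labels" in row.index and pd.notna(row["channel_labels"]):
        out["channel_labels"] = str(row["channel_labels"]).split(";")
    return out
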
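import numpy as np
import pytest

from vesicoloc import BinaryMask, ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_mask(on_pixels, shape=(4, 4), label="m"):
    """Binary mask from a list of (y, x) on-pixel coordinates."""
    values = np.zeros(shape, dtype=np.uint8)
    for y, x in on_pixels:
        values[y, x] = 1
    return BinaryMask(values=values, label=label, threshold_used=0.0)


def make_stack(arr, pixel_size_nm=100.0, z_spacing_nm=None, labels=None, **kw):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    labels = labels or [f"ch{i}" for i in range(arr.shape[0])]
    return ImageStack(
        intensities=arr,
        pixel_size_nm=pixel_size_nm,
        z_spacing_nm=z_spacing_nm,
        channel_labels=labels,
        **kw,
    )
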
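"""Reading and writing 3D volumes as multi-page TIFF stacks.

One TIFF page per z-slice; page order is slice order. Grey-value stacks are
accepted in uint8/uint16/int16/float32 sample formats and normalised to
unsigned 16-bit on read; everything is written back as uint16.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .volume import IntensityVolume, LabelVolume, convert_to_u16

__all__ = ["read_tiff_stack", "write_tiff_stack", "read_label_stack"]

_DTYPE_TO_FORMAT = {
    np.dtype(np.uint8): "u8",
    np.dtype(np.uint16): "u16",
    np.dtype(np.int16): "i16",
    np.dtype(np.float32): "f32",
}


def _load_pages(path) -> np.ndarray:
    if not os.path.exists(path):
        raise IOError(f"cannot read TIFF stack: no such file {path!r}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        if len(pages) == 0:
            raise ValueError(f"{path!r} contains no pages")
        first = pages[0]
        shape, dtype = first.shape, first.dtype
        if len(shape) != 2:
            raise ValueError(
                f"{path!r}: only single-channel grayscale pages are supported, "
                f"got page shape {shape} (e.g. RGB is not accepted)"
            )
        for i, page in enumerate(pages):
            if page.shape != shape or page.dtype != dtype:
                raise ValueError(
                    f"{path!r}: page {i} has shape {page.shape}/{page.dtype}, "
                    f"inconsistent with page 0 ({shape}/{dtype})"
                )
        data = tif.asarray()
    if data.ndim == 2:  # single-page stack
        data = data[np.newaxis, ...]
    return data


def read_tiff_stack(path, input_range=None) -> IntensityVolume:
    """Read a multi-page grayscale TIFF into an :class:`IntensityVolume`.

    uint8 pages are widened to 16-bit without rescaling (values stay in
    0-255); uint16 is read as-is. int16 and float32 stacks require
    ``input_range=(low, high)``: values are clipped to the range and mapped
    affinely onto 0-65535.
    """
    data = _load_pages(path)
    fmt = _DTYPE_TO_FORMAT.get(data.dtype)
    if fmt is None:
        raise ValueError(
            f"{path!r}: unsupported sample type {data.dtype}; "
            "expected uint8, uint16, int16 or float32"
        )
    return convert_to_u16(data, fmt, input_range=input_range)


def read_label_stack(path) -> LabelVolume:
    """Read a label map stored as an integer TIFF stack."""
    data = _load_pages(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path!r}: label stacks must have integer samples, got {data.dtype}")
    return LabelVolume(data.astype(np.int64))


def write_tiff_stack(volume_or_labels, path) -> str:
    """Write a volume or label map as a uint16 multi-page TIFF, one page per slice.

    Round-trips exactly: reading the file back reproduces the grid voxel for
    voxel. Label maps with more than 65535 segments do not fit the sample
    format and are rejected.
    """
    if isinstance(volume_or_labels, IntensityVolume):
        data = volume_or_labels.data
    elif isinstance(volume_or_labels, LabelVolume):
        data = volume_or_labels.labels
        if data.size and data.max() > 65535:
            raise ValueError(
                f"label map has max label {int(data.max())}, exceeding the "
                "65535 capacity of a uint16 TIFF stack"
            )
        data = data.astype(np.uint16)
    else:
        data = np.asarray(volume_or_labels)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {data.shape}")
        data = data.astype(np.uint16)
    try:
        tifffile.imwrite(path, data, photometric="minisblack")
    except OSError as exc:
        raise IOError(f"cannot write TIFF stack to {path!r}: {exc}") from exc
    return str(path)
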
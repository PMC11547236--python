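"""In-memory containers for grey-value volumes and label maps.

All volumes use (z, y, x) axis order, with z the slice (TIFF page) index.
Grey values are unsigned 16-bit attenuation surrogates; labels are
non-negative integers with 0 meaning background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityVolume",
    "LabelVolume",
    "convert_to_u16",
    "downsample",
]


@dataclass
class IntensityVolume:
    """A 3D grid of unsigned 16-bit grey values.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``, dtype ``uint16``.
    spacing
        Optional voxel spacing ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError(f"all dimensions must be positive, got {self.data.shape}")
        if self.data.dtype != np.uint16:
            if not (np.issubdtype(self.data.dtype, np.integer)
                    and self.data.min() >= 0 and self.data.max() <= 65535):
                raise ValueError(
                    f"volume data must be uint16 (or losslessly castable), got {self.data.dtype}"
                )
            self.data = self.data.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D grid of segment labels aligned voxel-for-voxel with a volume.

    Label 0 is background; segments are 1..K.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integers, got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def num_segments(self) -> int:
        """Largest label present (0 for an empty map)."""
        return int(self.labels.max()) if self.labels.size else 0

    def segment_sizes(self) -> list[int]:
        """Voxel count per label 1..K."""
        k = self.num_segments
        counts = np.bincount(self.labels.ravel(), minlength=k + 1)
        return counts[1:].tolist()


_SOURCE_FORMATS = {"u8", "u16", "i16", "f32"}


def convert_to_u16(data, source_format: str, input_range=None) -> IntensityVolume:
    """Convert a 3D grid to unsigned 16-bit storage.

    ``u8`` values are widened without rescaling (the output occupies 0-255),
    ``u16`` is the identity, and ``f32``/``i16`` values are clipped to the
    user-supplied ``input_range`` then affinely mapped so that ``low`` -> 0 and
    ``high`` -> 65535, rounding halves up.  No automatic range estimation is
    attempted for float data: the appropriate window depends on where the bone
    grey values sit and must be chosen by the user.
    """
    if source_format not in _SOURCE_FORMATS:
        raise ValueError(f"unknown source format {source_format!r}; expected one of {sorted(_SOURCE_FORMATS)}")
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {arr.shape}")

    if source_format == "u16":
        return IntensityVolume(arr.astype(np.uint16))
    if source_format == "u8":
        return IntensityVolume(arr.astype(np.uint16))

    if input_range is None:
        raise ValueError(f"input_range is required when converting from {source_format}")
    low, high = float(input_range[0]), float(input_range[1])
    if low >= high:
        raise ValueError(f"input_range must satisfy low < high, got ({low}, {high})")
    clipped = np.clip(arr.astype(np.float64), low, high)
    scaled = (clipped - low) / (high - low) * 65535.0
    return IntensityVolume(np.floor(scaled + 0.5).astype(np.uint16))


def downsample(volume: IntensityVolume, factor) -> IntensityVolume:
    """Block-mean downsampling by an integer factor per axis.

    Output shape is ``ceil(shape / factor)`` per axis; each output voxel is
    the mean of its source block, rounded half-up.  Edge blocks may be
    partial and average only the voxels they contain.
    """
    if np.isscalar(factor):
        factor = (factor, factor, factor)
    factor = tuple(int(f) for f in factor)
    if len(factor) != 3 or any(f < 1 for f in factor):
        raise ValueError(f"factor must be >= 1 on each of the three axes, got {factor}")
    if factor == (1, 1, 1):
        return IntensityVolume(volume.data.copy(), spacing=volume.spacing)

    sums = volume.data.astype(np.float64)
    counts = np.ones(volume.shape, dtype=np.float64)
    for axis, f in enumerate(factor):
        if f == 1:
            continue
        idx = np.arange(0, sums.shape[axis], f)
        sums = np.add.reduceat(sums, idx, axis=axis)
        counts = np.add.reduceat(counts, idx, axis=axis)
    means = sums / counts
    spacing = None
    if volume.spacing is not None:
        spacing = tuple(s * f for s, f in zip(volume.spacing, factor))
    return IntensityVolume(np.floor(means + 0.5).astype(np.uint16), spacing=spacing)
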
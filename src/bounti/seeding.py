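"""Seed construction: thresholding, component labeling, largest-NS selection.

The seed is the segmentation of fully disarticulated parts obtained at the
initial threshold: the superlevel set is decomposed into connected
components and the NS largest are kept, labeled 1..NS by descending size.
A manual label volume can replace the automatic seed, either keeping its
label identities (so touching segments stay distinct) or reduced to the
largest connected components of its support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import IntensityVolume, LabelVolume

__all__ = [
    "BinaryMask",
    "Seed",
    "threshold_mask",
    "label_components",
    "select_largest",
    "dilate_seed",
    "load_manual_seed",
    "connectivity_structure",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 boolean neighbourhood for 6-, 18- or 26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except (KeyError, ValueError):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity!r}") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class BinaryMask:
    """Superlevel set of a volume at a given threshold."""

    mask: np.ndarray
    threshold_used: int

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class Seed:
    """Initial segmentation from which all segments grow.

    ``segment_sizes[i]`` is the voxel count of label ``i + 1``. For automatic
    seeds the list is non-increasing: label 1 is the largest component.
    """

    labels: LabelVolume
    segment_sizes: list[int]
    provenance: str  # auto | manual_preserve | manual_largest
    dilated: bool = False

    @property
    def num_segments(self) -> int:
        return len(self.segment_sizes)


def threshold_mask(volume: IntensityVolume, t: int) -> BinaryMask:
    """Voxels with grey value >= t (inclusive convention)."""
    t = int(t)
    if not 0 <= t <= 65535:
        raise ValueError(f"threshold must be in [0, 65535], got {t}")
    return BinaryMask(mask=volume.data >= t, threshold_used=t)


def label_components(mask: BinaryMask, connectivity: int = 26):
    """Label the connected true-regions of a mask, largest first.

    Returns ``(LabelVolume, sizes)`` where labels are assigned 1..K in
    decreasing component size, ties broken by the scan order (z, y, x) of
    each component's first voxel, making the labeling deterministic.
    """
    structure = connectivity_structure(connectivity)
    raw, n = ndimage.label(mask.mask, structure=structure)
    if n == 0:
        return LabelVolume(np.zeros(mask.shape, dtype=np.int32)), []
    flat = raw.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    # scipy assigns raw labels in raster order of first encounter, so the raw
    # label index itself is the scan-order tiebreak
    order = np.lexsort((np.arange(n), -counts))
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    relabeled = remap[raw]
    sizes = counts[order].tolist()
    return LabelVolume(relabeled), sizes


def select_largest(labeled: LabelVolume, sizes: list[int], ns: int) -> Seed:
    """Retain the ``ns`` largest components, relabeled 1..ns by descending size.

    Components beyond the ``ns`` largest become background. If fewer than
    ``ns`` components exist, all are kept and a warning is issued.
    """
    ns = int(ns)
    if ns < 1:
        raise ValueError(f"number of segments must be >= 1, got {ns}")
    k = len(sizes)
    if k < ns:
        warnings.warn(
            f"requested {ns} segments but only {k} connected components exist; "
            "keeping all of them",
            stacklevel=2,
        )
    keep = min(ns, k)
    labels = labeled.labels
    out = np.where(labels <= keep, labels, 0).astype(np.int32)
    return Seed(
        labels=LabelVolume(out),
        segment_sizes=list(sizes[:keep]),
        provenance="auto",
        dilated=False,
    )


_SENTINEL = np.int32(np.iinfo(np.int32).max)
_FULL_26 = np.ones((3, 3, 3), dtype=bool)


def dilate_seed(seed: Seed, mask_limit: BinaryMask | None = None) -> Seed:
    """Expand each segment by its one-voxel 26-neighbourhood shell.

    A shell voxel adjacent to more than one segment is contested and stays
    background, so dilation can never fuse segments. Existing labels are
    never overwritten. If ``mask_limit`` is given, only mask-true voxels may
    be claimed.
    """
    labels = seed.labels.labels.astype(np.int32)
    sent = np.where(labels > 0, labels, _SENTINEL)
    lo = ndimage.minimum_filter(sent, footprint=_FULL_26, mode="constant", cval=_SENTINEL)
    hi = ndimage.maximum_filter(labels, footprint=_FULL_26, mode="constant", cval=0)
    claimable = (labels == 0) & (lo < _SENTINEL) & (lo == hi)
    if mask_limit is not None:
        if mask_limit.shape != seed.labels.shape:
            raise ValueError("mask_limit shape does not match the seed")
        claimable &= mask_limit.mask
    out = labels.copy()
    out[claimable] = lo[claimable]
    counts = np.bincount(out.ravel(), minlength=seed.num_segments + 1)
    return Seed(
        labels=LabelVolume(out),
        segment_sizes=counts[1 : seed.num_segments + 1].tolist(),
        provenance=seed.provenance,
        dilated=True,
    )


def load_manual_seed(labels: LabelVolume, mode: str, ns: int, connectivity: int = 26) -> Seed:
    """Build a seed from a user-supplied label volume.

    mode ``preserve``: labels are used exactly as given, so segments in
    contact keep their distinct identities — the case an automatic threshold
    seed cannot produce. mode ``largest``: label identities are discarded,
    the non-zero support is re-labeled by connected components and the
    ``ns`` largest are retained.
    """
    if mode not in ("preserve", "largest"):
        raise ValueError(f"seed mode must be 'preserve' or 'largest', got {mode!r}")
    arr = labels.labels
    if not arr.any():
        raise ValueError("manual seed is empty (all background)")
    if mode == "preserve":
        present = np.unique(arr)
        present = present[present > 0]
        counts = np.bincount(arr.ravel(), minlength=int(present.max()) + 1)
        sizes = [int(counts[v]) for v in range(1, int(present.max()) + 1)]
        return Seed(
            labels=LabelVolume(arr.copy()),
            segment_sizes=sizes,
            provenance="manual_preserve",
            dilated=False,
        )
    mask = BinaryMask(mask=arr > 0, threshold_used=0)
    relabeled, sizes = label_components(mask, connectivity=connectivity)
    seed = select_largest(relabeled, sizes, ns)
    seed.provenance = "manual_largest"
    return seed
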
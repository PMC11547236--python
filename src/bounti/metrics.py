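"""Per-segment Dice scoring of a segmentation against a reference.

Segments are matched by overlap, not by label value, so a correct
segmentation with permuted labels still scores 1. Reference segments that
no result segment matches count as 0 in the mean-with-missing average and
are omitted from the mean-without-missing average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabelVolume

__all__ = ["DiceReport", "dice", "dice_report"]


@dataclass
class DiceReport:
    """Per-reference-segment Dice coefficients and their two averages."""

    per_segment: dict[int, float]
    mean_with_missing: float
    mean_without_missing: float
    matching: dict[int, int]  # reference label -> matched result label


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two voxel sets."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice is undefined for two empty sets")
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_report(result: LabelVolume, reference: LabelVolume) -> DiceReport:
    """Score a segmentation against a reference labeling, segment by segment.

    Result segments are assigned to reference segments greedily on
    descending voxel overlap, each side matched at most once (ties broken
    by smaller reference then smaller result label, deterministically).
    """
    res = result.labels
    ref = reference.labels
    if res.shape != ref.shape:
        raise ValueError(f"shapes differ: {res.shape} vs {ref.shape}")
    kr = int(ref.max())
    if kr == 0:
        raise ValueError("reference labeling has no segments")
    ks = int(res.max())

    ref_sizes = np.bincount(ref.ravel(), minlength=kr + 1)
    res_sizes = np.bincount(res.ravel(), minlength=ks + 1)

    # joint histogram of (reference, result) labels over co-foreground voxels
    both = (ref > 0) & (res > 0)
    pair = ref[both].astype(np.int64) * (ks + 1) + res[both].astype(np.int64)
    overlap = np.bincount(pair, minlength=(kr + 1) * (ks + 1)).reshape(kr + 1, ks + 1)

    entries = [
        (int(overlap[r, s]), r, s)
        for r in range(1, kr + 1)
        for s in range(1, ks + 1)
        if overlap[r, s] > 0
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))

    matching: dict[int, int] = {}
    used_result: set[int] = set()
    for _, r, s in entries:
        if r in matching or s in used_result:
            continue
        matching[r] = s
        used_result.add(s)

    per_segment: dict[int, float] = {}
    matched_scores = []
    for r in range(1, kr + 1):
        if r in matching:
            s = matching[r]
            score = 2.0 * int(overlap[r, s]) / (int(ref_sizes[r]) + int(res_sizes[s]))
            matched_scores.append(score)
        else:
            score = 0.0
        per_segment[r] = score

    all_scores = list(per_segment.values())
    return DiceReport(
        per_segment=per_segment,
        mean_with_missing=float(np.mean(all_scores)),
        mean_without_missing=float(np.mean(matched_scores)) if matched_scores else 0.0,
        matching=matching,
    )
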
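"""Boundary-preserving threshold iteration: schedule and growth engine.

The algorithm descends from an initial threshold IT (at which the parts of
the structure are disarticulated) to a target threshold TT (at which the
bone definition is acceptable) in NI equal steps. At each iteration the
superlevel set of the current threshold is computed and every mask voxel
connected to an existing segment is claimed by a simultaneous multi-source
breadth-first expansion from all segments; wavefronts meeting head-on form
the inter-segment boundary. Segments separated in the seed therefore remain
separated throughout, while the final union reaches the definition of the
low target threshold.

Schedule arithmetic:

    TS  = (IT - TT) / NI          (per-iteration threshold decrement)
    CIT = IT - TS * CI            (threshold at iteration CI = 0..NI)

CIT values are rounded to the nearest integer grey value; the final entry
is forced to TT exactly. The integer step reported for display is
``floor(TS)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .seeding import (
    BinaryMask,
    Seed,
    connectivity_structure,
    dilate_seed,
    label_components,
    select_largest,
    threshold_mask,
)
from .volume import IntensityVolume, LabelVolume

__all__ = [
    "BountiParams",
    "ThresholdSchedule",
    "SegmentationResult",
    "build_schedule",
    "grow_once",
    "run",
    "extract_seed_preview",
]

logger = logging.getLogger(__name__)

_SENTINEL = np.int32(np.iinfo(np.int32).max)


@dataclass(frozen=True)
class BountiParams:
    """Algorithm parameters.

    Parameters
    ----------
    initial_threshold
        IT, grey value: high threshold whose superlevel set separates the
        anatomical parts; source of the seed.
    target_threshold
        TT, grey value: low threshold with the desired bone definition;
        endpoint of the schedule. Must satisfy ``TT <= IT``.
    num_iterations
        NI >= 1: number of threshold steps from IT down to TT.
    num_segments
        NS >= 1: number of largest seed components retained.
    connectivity
        Voxel neighbourhood (6, 18 or 26) for component labeling and growth.
    dilate
        Expand each seed segment by a one-voxel shell before iterating.
    """

    initial_threshold: int
    target_threshold: int
    num_iterations: int
    num_segments: int
    connectivity: int = 26
    dilate: bool = False

    def __post_init__(self) -> None:
        it, tt = int(self.initial_threshold), int(self.target_threshold)
        if not (0 <= tt <= it <= 65535):
            raise ValueError(
                f"thresholds must satisfy 0 <= TT <= IT <= 65535, "
                f"got IT={it}, TT={tt}"
            )
        if int(self.num_iterations) < 1:
            raise ValueError(f"number of iterations must be >= 1, got {self.num_iterations}")
        if int(self.num_segments) < 1:
            raise ValueError(f"number of segments must be >= 1, got {self.num_segments}")
        if int(self.num_segments) > 65535:
            raise ValueError("number of segments is capped at 65535 (uint16 label export)")
        if int(self.connectivity) not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


@dataclass(frozen=True)
class ThresholdSchedule:
    """Ordered per-iteration thresholds CIT(0..NI) with step TS.

    ``thresholds[0] == IT`` and ``thresholds[NI] == TT`` exactly; the
    sequence is non-increasing with ``NI + 1`` entries.
    """

    step: float
    thresholds: tuple[int, ...]

    @property
    def num_iterations(self) -> int:
        return len(self.thresholds) - 1

    @property
    def integer_step(self) -> int:
        """Floored integer step, the value reported for display."""
        return math.floor(self.step)


def build_schedule(params: BountiParams) -> ThresholdSchedule:
    """Compute the threshold sequence from IT down to TT in NI equal steps."""
    it = int(params.initial_threshold)
    tt = int(params.target_threshold)
    ni = int(params.num_iterations)
    ts = (it - tt) / ni
    thresholds = [int(math.floor(it - ts * ci + 0.5)) for ci in range(ni + 1)]
    thresholds[-1] = tt  # guard against float rounding at the endpoint
    return ThresholdSchedule(step=ts, thresholds=tuple(thresholds))


def grow_once(
    labels: LabelVolume | np.ndarray,
    volume: IntensityVolume,
    cit: int,
    connectivity: int = 26,
) -> LabelVolume:
    """One growth pass: claim all mask voxels reachable from the segments.

    The mask is the superlevel set at ``cit``. All segments expand as
    simultaneous breadth-first wavefronts, one voxel layer per round; each
    unclaimed mask voxel is taken by the first wavefront to reach it, and a
    voxel reached by several wavefronts in the same round goes to the
    smallest label. Existing labels are never reassigned; mask components
    touching no segment stay background.
    """
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    if arr.shape != volume.shape:
        raise ValueError(f"label shape {arr.shape} does not match volume shape {volume.shape}")
    mask = volume.data >= int(cit)
    footprint = connectivity_structure(connectivity)
    out = arr.astype(np.int32, copy=True)
    sent = np.where(out > 0, out, _SENTINEL)
    while True:
        cand = ndimage.minimum_filter(sent, footprint=footprint, mode="constant", cval=_SENTINEL)
        newly = (out == 0) & mask & (cand < _SENTINEL)
        if not newly.any():
            break
        out[newly] = cand[newly]
        sent[newly] = cand[newly]
    return LabelVolume(out)


@dataclass
class SegmentationResult:
    """Final segmentation plus the full provenance of the run."""

    labels: LabelVolume
    seed: Seed
    params: BountiParams
    schedule: ThresholdSchedule
    per_segment_sizes: list[int]
    snapshots: dict[int, LabelVolume] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def num_segments(self) -> int:
        return len(self.per_segment_sizes)

    def summary(self) -> dict:
        """Machine-readable run report."""
        return {
            "params": {
                "initial_threshold": self.params.initial_threshold,
                "target_threshold": self.params.target_threshold,
                "num_iterations": self.params.num_iterations,
                "num_segments": self.params.num_segments,
                "connectivity": self.params.connectivity,
                "dilate": self.params.dilate,
            },
            "schedule": {
                "step": self.schedule.step,
                "integer_step": self.schedule.integer_step,
                "thresholds": list(self.schedule.thresholds),
            },
            "seed": {
                "provenance": self.seed.provenance,
                "dilated": self.seed.dilated,
                "segment_sizes": self.seed.segment_sizes,
            },
            "per_segment_sizes": self.per_segment_sizes,
            "warnings": self.warnings,
        }


def _build_auto_seed(volume: IntensityVolume, params: BountiParams) -> Seed:
    mask = threshold_mask(volume, params.initial_threshold)
    if not mask.mask.any():
        raise ValueError(
            f"no voxel reaches the initial threshold {params.initial_threshold}; "
            "the seed is empty — lower the initial threshold"
        )
    labeled, sizes = label_components(mask, connectivity=params.connectivity)
    return select_largest(labeled, sizes, params.num_segments)


def extract_seed_preview(volume: IntensityVolume, params: BountiParams) -> Seed:
    """The seed exactly as :func:`run` would construct it, without iterating.

    Useful for checking that the initial threshold disarticulates the
    structure into the expected parts before committing to a full run.
    """
    seed = _build_auto_seed(volume, params)
    if params.dilate:
        seed = dilate_seed(seed)
    return seed


def run(
    volume: IntensityVolume,
    params: BountiParams,
    manual_seed: Seed | None = None,
    snapshot_at=None,
) -> SegmentationResult:
    """Run the full boundary-preserving threshold iteration.

    The seed is built from the initial threshold (or taken from
    ``manual_seed``), optionally dilated, then grown once per scheduled
    threshold from iteration 1 to NI. Iteration 0 is the seed state.
    ``snapshot_at`` is an optional collection of iteration indices at which
    to record the intermediate labeling.

    Raises
    ------
    ValueError
        If no voxel reaches the initial threshold (empty seed): lower IT.
    """
    schedule = build_schedule(params)
    run_warnings: list[str] = []

    if manual_seed is not None:
        if manual_seed.labels.shape != volume.shape:
            raise ValueError(
                f"manual seed shape {manual_seed.labels.shape} does not match "
                f"volume shape {volume.shape}"
            )
        seed = manual_seed
        if params.dilate and not seed.dilated:
            seed = dilate_seed(seed)
    else:
        seed = _build_auto_seed(volume, params)
        if seed.num_segments < params.num_segments:
            run_warnings.append(
                f"seed has {seed.num_segments} components, fewer than the "
                f"{params.num_segments} requested"
            )
        if params.dilate:
            seed = dilate_seed(seed)

    snapshot_at = frozenset(int(i) for i in snapshot_at) if snapshot_at is not None else frozenset()
    snapshots: dict[int, LabelVolume] = {}

    labels = LabelVolume(seed.labels.labels.astype(np.int32, copy=True))
    if 0 in snapshot_at:
        snapshots[0] = LabelVolume(labels.labels.copy())

    for ci in range(1, schedule.num_iterations + 1):
        labels = grow_once(labels, volume, schedule.thresholds[ci], params.connectivity)
        if ci in snapshot_at:
            snapshots[ci] = LabelVolume(labels.labels.copy())
        logger.debug("iteration %d/%d at threshold %d", ci, schedule.num_iterations,
                     schedule.thresholds[ci])

    k = seed.num_segments
    counts = np.bincount(labels.labels.ravel(), minlength=k + 1)
    per_segment_sizes = counts[1 : k + 1].tolist()

    return SegmentationResult(
        labels=labels,
        seed=seed,
        params=params,
        schedule=schedule,
        per_segment_sizes=per_segment_sizes,
        snapshots=snapshots,
        warnings=run_warnings,
    )
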
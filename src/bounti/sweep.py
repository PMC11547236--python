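"""Parameter-sensitivity sweeps: initial threshold, iteration count, file size.

Three reproducible experiments over a fixed volume:

* ``initial_threshold`` — rerun with each IT value; with ``keep_step`` the
  iteration count is recomputed as NI = (IT - TT) / step (exact division
  enforced) so the step size does not confound the threshold choice.
* ``iterations`` — rerun with each NI between fixed IT and TT.
* ``size`` — downsample by each factor and rerun; wall time is recorded in
  the summary for the user's information only (hardware-dependent).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .core import BountiParams, SegmentationResult, run
from .volume import IntensityVolume, downsample

__all__ = ["SweepSpec", "SweepRow", "run_sweep", "iterations_for_step"]

_MODES = ("initial_threshold", "iterations", "size")


@dataclass(frozen=True)
class SweepSpec:
    """One sensitivity experiment: which parameter to vary and over what values."""

    mode: str
    values: tuple
    fixed: BountiParams
    keep_step: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"sweep mode must be one of {_MODES}, got {self.mode!r}")
        if not self.values:
            raise ValueError("sweep values must be non-empty")
        if list(self.values) != sorted(self.values):
            raise ValueError("sweep values must be sorted ascending")
        if self.keep_step is not None and self.mode != "initial_threshold":
            raise ValueError("keep_step is only valid for initial_threshold sweeps")


def iterations_for_step(initial_threshold: int, target_threshold: int, step: int) -> int:
    """NI such that (IT - TT) / NI equals the requested step exactly."""
    span = int(initial_threshold) - int(target_threshold)
    step = int(step)
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if span % step != 0:
        raise ValueError(
            f"initial threshold {initial_threshold} does not admit an integer "
            f"iteration count at step {step} (span {span} is not divisible)"
        )
    return span // step


@dataclass
class SweepRow:
    """Outcome of one sweep run, for the summary table."""

    value: object
    params: BountiParams
    result: SegmentationResult
    wall_time_s: float

    def as_record(self) -> dict:
        return {
            "swept_value": self.value,
            "initial_threshold": self.params.initial_threshold,
            "target_threshold": self.params.target_threshold,
            "num_iterations": self.params.num_iterations,
            "num_segments_requested": self.params.num_segments,
            "num_segments_found": self.result.num_segments,
            "integer_step": self.result.schedule.integer_step,
            "segment_sizes": self.result.per_segment_sizes,
            "wall_time_s": self.wall_time_s,
        }


def _params_for(spec: SweepSpec, value) -> BountiParams:
    base = spec.fixed
    if spec.mode == "initial_threshold":
        ni = base.num_iterations
        if spec.keep_step is not None:
            ni = iterations_for_step(value, base.target_threshold, spec.keep_step)
        return BountiParams(
            initial_threshold=int(value),
            target_threshold=base.target_threshold,
            num_iterations=ni,
            num_segments=base.num_segments,
            connectivity=base.connectivity,
            dilate=base.dilate,
        )
    if spec.mode == "iterations":
        return BountiParams(
            initial_threshold=base.initial_threshold,
            target_threshold=base.target_threshold,
            num_iterations=int(value),
            num_segments=base.num_segments,
            connectivity=base.connectivity,
            dilate=base.dilate,
        )
    return base  # size mode: params unchanged, the volume varies


def run_sweep(spec: SweepSpec, volume: IntensityVolume) -> list[SweepRow]:
    """Execute every run of a sweep, in value order."""
    rows = []
    for value in spec.values:
        params = _params_for(spec, value)
        vol = downsample(volume, value) if spec.mode == "size" else volume
        t0 = time.perf_counter()
        result = run(vol, params)
        elapsed = time.perf_counter() - t0
        rows.append(SweepRow(value=value, params=params, result=result, wall_time_s=elapsed))
    return rows
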
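"""Synthetic test volumes with the intensity structure the algorithm assumes.

A phantom is a set of high-intensity spherical bodies (bone) joined by
intermediate-intensity cylindrical bridges (sutures) over a low-intensity
background (soft tissue/air), optionally degraded by Gaussian blur (scan
sharpness) and additive Gaussian noise (contrast resolution). Ground truth
assigns each body's voxels its own label and splits bridge voxels by
nearest body centre — the fair reference for a growth whose wavefront
boundary approximates equidistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import IntensityVolume, LabelVolume

__all__ = ["PhantomSpec", "make_phantom", "two_body_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of a synthetic volume.

    ``bodies`` is a list of ``(centre, radius, core_intensity)`` with centre
    in (z, y, x) voxel coordinates; ``bridges`` is a list of
    ``(body_a, body_b, thickness, bridge_intensity)`` joining two bodies by
    index with a cylinder of the given diameter. Intensities must satisfy
    core > bridge > background for the phantom to have the structure the
    algorithm assumes. ``noise_sigma`` (grey values) and ``blur_sigma``
    (voxels) emulate scan quality; noise is applied after blur.
    """

    size: tuple[int, int, int]
    bodies: tuple = ()
    bridges: tuple = ()
    background_intensity: int = 5000
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.size) != 3 or any(s < 1 for s in self.size):
            raise ValueError(f"size must be three positive dimensions, got {self.size}")
        for centre, radius, core in self.bodies:
            if any(c - radius < 0 or c + radius > s - 1
                   for c, s in zip(centre, self.size)):
                raise ValueError(f"body at {centre} (r={radius}) does not fit inside {self.size}")
            if core <= self.background_intensity:
                raise ValueError("core intensity must exceed the background intensity")
        for a, b, thickness, bridge in self.bridges:
            if not (0 <= a < len(self.bodies) and 0 <= b < len(self.bodies)) or a == b:
                raise ValueError(f"bridge ({a}, {b}) does not join two distinct bodies")
            if not (self.background_intensity < bridge < min(self.bodies[a][2], self.bodies[b][2])):
                raise ValueError("bridge intensity must lie between background and both cores")
        centres = [np.asarray(c, dtype=float) for c, _, _ in self.bodies]
        radii = [r for _, r, _ in self.bodies]
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                if np.linalg.norm(centres[i] - centres[j]) <= radii[i] + radii[j]:
                    raise ValueError(f"bodies {i} and {j} overlap")


def _sphere_mask(shape, centre, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = centre
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _cylinder_mask(shape, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the open segment p0-p1 (caps excluded)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length2 = float(axis @ axis)
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"), axis=-1)
    rel = grid - p0
    t = (rel @ axis) / length2
    perp = rel - t[..., None] * axis
    dist2 = np.einsum("...i,...i", perp, perp)
    return (dist2 <= radius**2) & (t >= 0.0) & (t <= 1.0)


def make_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume]:
    """Render a phantom and its ground-truth labeling.

    The clean render is piecewise constant (background / bridge / core),
    then Gaussian blur of ``blur_sigma`` voxels and additive Gaussian noise
    of ``noise_sigma`` grey values are applied, the result clipped to
    [0, 65535]. Identical specs (including ``rng_seed``) render identical
    volumes. Ground truth labels bodies 1..N in list order; bridge voxels
    outside every core go to the nearest body centre.
    """
    shape = tuple(spec.size)
    clean = np.full(shape, spec.background_intensity, dtype=np.float64)
    truth = np.zeros(shape, dtype=np.int32)

    body_masks = [_sphere_mask(shape, centre, radius) for centre, radius, _ in spec.bodies]
    bridge_support = np.zeros(shape, dtype=bool)
    for a, b, thickness, bridge_intensity in spec.bridges:
        cyl = _cylinder_mask(shape, spec.bodies[a][0], spec.bodies[b][0], thickness / 2.0)
        clean[cyl & (clean < bridge_intensity)] = bridge_intensity
        bridge_support |= cyl
    for i, (mask, (_, _, core)) in enumerate(zip(body_masks, spec.bodies)):
        clean[mask] = core
        truth[mask] = i + 1

    # bridge voxels outside every core: nearest body centre owns them
    loose = bridge_support & (truth == 0)
    if loose.any() and spec.bodies:
        centres = np.asarray([c for c, _, _ in spec.bodies], dtype=float)
        coords = np.argwhere(loose).astype(float)
        d2 = ((coords[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        truth[loose] = d2.argmin(axis=1) + 1

    rendered = clean
    if spec.blur_sigma > 0:
        rendered = ndimage.gaussian_filter(rendered, sigma=spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        rendered = rendered + rng.normal(0.0, spec.noise_sigma, size=shape)
    rendered = np.clip(np.floor(rendered + 0.5), 0, 65535).astype(np.uint16)
    return IntensityVolume(rendered), LabelVolume(truth)


def two_body_spec(
    size: tuple[int, int, int] = (48, 48, 48),
    radius: int = 6,
    separation: int = 20,
    core_intensity: int = 40000,
    bridge_intensity: int = 30000,
    background_intensity: int = 5000,
    bridge_thickness: float = 3.0,
    noise_sigma: float = 0.0,
    blur_sigma: float = 0.0,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Two spheres joined by one bridge along the x axis.

    The canonical configuration: with an initial threshold between bridge
    and core intensity the seed has exactly two components, while a direct
    threshold at any value at or below the bridge intensity yields a single
    connected component.
    """
    cz, cy = size[0] // 2, size[1] // 2
    cx = size[2] // 2
    half = separation // 2
    bodies = (
        ((cz, cy, cx - half), radius, core_intensity),
        ((cz, cy, cx + separation - half), radius, core_intensity),
    )
    bridges = ((0, 1, bridge_thickness, bridge_intensity),)
    return PhantomSpec(
        size=size,
        bodies=bodies,
        bridges=bridges,
        background_intensity=background_intensity,
        noise_sigma=noise_sigma,
        blur_sigma=blur_sigma,
        rng_seed=rng_seed,
    )
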
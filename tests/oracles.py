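"""Independent pure-Python oracles for cross-checking the engine.

Deliberately naive: explicit neighbour offsets, Python sets and deques,
no shared code with the package. Only usable at small volume sizes.
"""

from collections import deque
from itertools import product

import numpy as np


def neighbour_offsets(connectivity):
    offs = []
    for dz, dy, dx in product((-1, 0, 1), repeat=3):
        if (dz, dy, dx) == (0, 0, 0):
            continue
        manhattan = abs(dz) + abs(dy) + abs(dx)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offs.append((dz, dy, dx))
    return offs


def flood_components(mask, connectivity):
    """Connected components of a boolean array as lists of voxel tuples,
    in order of first-voxel raster scan."""
    mask = np.asarray(mask, dtype=bool)
    offs = neighbour_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for idx in product(*(range(s) for s in mask.shape)):
        if not mask[idx] or seen[idx]:
            continue
        comp = []
        queue = deque([idx])
        seen[idx] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for off in offs:
                w = tuple(a + b for a, b in zip(v, off))
                if any(c < 0 or c >= s for c, s in zip(w, mask.shape)):
                    continue
                if mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(comp)
    return components


def naive_grow(labels, data, cit, connectivity):
    """Level-synchronous multi-source BFS with smallest-label tie-breaking.

    Re-derives one growth pass from its definition: per BFS level, every
    unlabeled mask voxel adjacent to a voxel labeled in an earlier level
    takes the smallest such neighbouring label.
    """
    labels = np.asarray(labels)
    data = np.asarray(data)
    mask = data >= cit
    offs = neighbour_offsets(connectivity)
    out = labels.copy()
    while True:
        claims = {}
        for idx in product(*(range(s) for s in out.shape)):
            if out[idx] != 0 or not mask[idx]:
                continue
            best = None
            for off in offs:
                w = tuple(a + b for a, b in zip(idx, off))
                if any(c < 0 or c >= s for c, s in zip(w, out.shape)):
                    continue
                if out[w] > 0 and (best is None or out[w] < best):
                    best = out[w]
            if best is not None:
                claims[idx] = best
        if not claims:
            return out
        for idx, lab in claims.items():
            out[idx] = lab


def naive_final_union(data, tt, seed_support, connectivity):
    """Voxel set of the expected final union: the TT-superlevel components
    that intersect the seed support."""
    data = np.asarray(data)
    seed_support = np.asarray(seed_support, dtype=bool)
    union = np.zeros(data.shape, dtype=bool)
    for comp in flood_components(data >= tt, connectivity):
        if any(seed_support[v] for v in comp):
            for v in comp:
                union[v] = True
    return union
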
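"""Independent brute-force oracles used to pin down the fast implementations.

These deliberately share no code with the package: the Euler oracle builds
the explicit closed cell complex as Python sets, and the labeling oracle is
a plain breadth-first flood fill over coordinate tuples.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def euler_brute_force(mask: np.ndarray) -> int:
    """chi = V - E + F - C by enumerating the cells of the closed complex.

    Each foreground voxel contributes its 8 vertices, 12 edges, 6 faces and
    1 cube; shared cells are deduplicated by set membership.  Cells are keyed
    by their minimal corner plus an orientation tag.
    """
    verts: set = set()
    edges: set = set()
    faces: set = set()
    cubes: set = set()
    for z, y, x in zip(*np.nonzero(np.asarray(mask, dtype=bool))):
        z, y, x = int(z), int(y), int(x)
        cubes.add((z, y, x))
        for dz, dy, dx in product((0, 1), repeat=3):
            verts.add((z + dz, y + dy, x + dx))
        # edges along each axis: minimal corner in the transverse directions
        for dy, dx in product((0, 1), repeat=2):
            edges.add(("z", z, y + dy, x + dx))
        for dz, dx in product((0, 1), repeat=2):
            edges.add(("y", z + dz, y, x + dx))
        for dz, dy in product((0, 1), repeat=2):
            edges.add(("x", z + dz, y + dy, x))
        # faces perpendicular to each axis
        for d in (0, 1):
            faces.add(("z", z + d, y, x))
            faces.add(("y", z, y + d, x))
            faces.add(("x", z, y, x + d))
    return len(verts) - len(edges) + len(faces) - len(cubes)


_NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def flood_fill_partition(mask: np.ndarray) -> set[frozenset]:
    """Partition of foreground voxels into 26-connected components.

    Stack/queue-based flood fill; returns a set of frozensets of (z, y, x)
    tuples so the comparison is order-free.
    """
    mask = np.asarray(mask, dtype=bool)
    remaining = {tuple(int(v) for v in p) for p in np.argwhere(mask)}
    parts: set[frozenset] = set()
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        remaining.discard(seed)
        queue = deque([seed])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in _NEIGHBORS_26:
                q = (z + dz, y + dy, x + dx)
                if q in remaining:
                    remaining.discard(q)
                    comp.add(q)
                    queue.append(q)
        parts.add(frozenset(comp))
    return parts


def labeling_to_partition(labels: np.ndarray) -> set[frozenset]:
    """Convert a label image into the same order-free partition form."""
    labels = np.asarray(labels)
    parts: set[frozenset] = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        parts.add(frozenset(tuple(int(v) for v in p) for p in np.argwhere(labels == lab)))
    return parts
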
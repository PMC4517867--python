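"""Hard-sphere steric model with uniform-grid clash detection.

Two atoms clash when their distance falls below ``collision_factor`` times
the sum of their van der Waals radii.  Pairs that can never meaningfully
clash — atoms of the same rigid body, atoms within three covalent bonds,
and the atoms of a declared hydrogen bond — are excluded.  A uniform
spatial grid with cell edge equal to the largest possible clash distance
restricts the search to neighboring cells; the result is identical to the
all-pairs check.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClashModel", "DEFAULT_RADII", "build_exclusions",
           "detect_clash", "all_clashes"]

# Conventional van der Waals radii, Å.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
                 "P": 1.80}
_FALLBACK_RADIUS = 1.70


@dataclass
class ClashModel:
    """Per-atom radii, global collision factor and excluded pairs."""

    radii: np.ndarray                       # per-atom vdW radius, Å
    collision_factor: float = 0.75
    excluded_pairs: set = field(default_factory=set)

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if not (self.radii > 0).all():
            raise ValueError("all radii must be positive")
        if not (0.0 < self.collision_factor <= 1.0):
            raise ValueError("collision_factor must be in (0, 1]")

    @classmethod
    def from_topology(cls, topology, collision_factor: float = 0.75,
                      excluded_pairs=None, radii_table=None):
        table = dict(DEFAULT_RADII)
        if radii_table:
            table.update(radii_table)
        radii = np.array([table.get(a.element, _FALLBACK_RADIUS)
                          for a in topology.atoms])
        return cls(radii=radii, collision_factor=collision_factor,
                   excluded_pairs=set(excluded_pairs or ()))


def build_exclusions(topology, tree=None, constraints=()) -> set:
    """Pairs never tested for clashes.

    Same-rigid-body pairs (their distance is fixed), pairs within three
    covalent bonds (fixed or governed by the torsion itself), and the
    donor/hydrogen/acceptor pairs of each declared hydrogen bond (which sit
    below vdW contact by design).
    """
    excl = set()
    adj = topology.adjacency()
    for a in range(topology.n_atoms):
        # BFS to depth 3 over the covalent graph
        dist = {a: 0}
        queue = deque([a])
        while queue:
            x = queue.popleft()
            if dist[x] == 3:
                continue
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    queue.append(y)
        for y, d in dist.items():
            if y != a:
                excl.add((min(a, y), max(a, y)))
    if tree is not None:
        for body in tree.bodies:
            atoms = sorted(body.atom_ids)
            for i, x in enumerate(atoms):
                for y in atoms[i + 1:]:
                    excl.add((x, y))
    for hb in constraints:
        for x, y in ((hb.donor, hb.hydrogen), (hb.donor, hb.acceptor),
                     (hb.hydrogen, hb.acceptor)):
            excl.add((min(x, y), max(x, y)))
    return excl


def _grid_index(coords: np.ndarray, cell: float):
    keys = np.floor(coords / cell).astype(np.int64)
    grid: dict[tuple, list[int]] = {}
    for idx, key in enumerate(map(tuple, keys)):
        grid.setdefault(key, []).append(idx)
    return keys, grid

_NEIGHBOR_OFFSETS = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                     for dz in (-1, 0, 1)]


def _iter_candidate_pairs(coords: np.ndarray, cutoff_matrix_max: float):
    """Yield candidate (i, j) pairs via neighbor-cell search."""
    cell = max(cutoff_matrix_max, 1e-6)
    keys, grid = _grid_index(coords, cell)
    for key, members in grid.items():
        for off in _NEIGHBOR_OFFSETS:
            nkey = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            others = grid.get(nkey)
            if others is None:
                continue
            for i in members:
                for j in others:
                    if i < j:
                        yield i, j


def detect_clash(coordinates: np.ndarray, model: ClashModel):
    """First clashing pair ``(i, j, distance)`` or ``None`` if clash-free."""
    for hit in _clashes(coordinates, model, first_only=True):
        return hit
    return None


def all_clashes(coordinates: np.ndarray, model: ClashModel):
    """All clashing pairs, as a sorted list of ``(i, j, distance)``."""
    return sorted(_clashes(coordinates, model, first_only=False))


def _clashes(coordinates, model, first_only):
    coords = np.asarray(coordinates, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    if n < 2:
        return
    cf = model.collision_factor
    max_cut = 2.0 * cf * float(model.radii.max())
    excl = model.excluded_pairs
    for i, j in _iter_candidate_pairs(coords, max_cut):
        if (i, j) in excl:
            continue
        cut = cf * (model.radii[i] + model.radii[j])
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < cut:
            yield (i, j, d)
            if first_only:
                return
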
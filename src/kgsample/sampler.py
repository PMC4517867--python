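"""Shell-stratified, RRT-like exploration of the constraint manifold.

The pool of accepted conformations is stratified into spherical shells of
RMSD from the start structure.  Each iteration draws an entirely random
torsion vector as a guide, picks a uniformly random non-empty shell, seeds
from the pool member of that shell closest to the guide, and proposes a
nullspace-projected random perturbation capped at a small per-DoF rotation.
Proposals are rejected on steric clash, on hydrogen-bond drift beyond
tolerance, or on leaving the exploration sphere; everything else enters the
pool.  Selecting seeds from sparsely populated outer shells keeps the
ensemble diffusing outward instead of oversampling the start basin.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import Conformation, KinematicTree, forward_kinematics
from .nullspace import (NullspaceBasis, compute_jacobian,
                        constraint_violation, find_cycles, max_drift,
                        nullspace_basis, project)
from .steric import ClashModel, detect_clash
from .structure_io import write_manifest, write_pdb

__all__ = ["SamplingConfig", "SamplePool", "random_conformation",
           "select_seed", "propose_step", "run"]


@dataclass
class SamplingConfig:
    """Run parameters; defaults are the standard operating point of the method.

    ``exploration_radius`` (Å RMSD from the start) bounds the pool,
    subdivided into shells of ``shell_width`` (100 shells at defaults);
    ``max_rotation`` caps the realized per-DoF move of one step (degrees);
    ``collision_factor`` scales vdW radii during clash detection and
    ``drift_tolerance`` bounds the allowed hydrogen-bond distance drift.
    """

    n_samples: int = 20000
    exploration_radius: float = 20.0
    shell_width: float = 0.2
    max_rotation: float = 0.29
    collision_factor: float = 0.75
    drift_tolerance: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if self.exploration_radius <= 0 or self.shell_width <= 0:
            raise ValueError("exploration radius and shell width must be > 0")

    @property
    def n_shells(self) -> int:
        return int(math.ceil(self.exploration_radius / self.shell_width))


@dataclass
class Sample:
    id: int
    q: np.ndarray
    coordinates: np.ndarray
    parent_id: int
    shell_index: int
    rmsd_from_init: float
    accepted_step_count: int


class SamplePool:
    """Accepted conformations stratified by RMSD shell."""

    def __init__(self, tree: KinematicTree, config: SamplingConfig,
                 metric_atoms: np.ndarray):
        self.tree = tree
        self.config = config
        self.metric_atoms = metric_atoms
        self.samples: list[Sample] = []
        self.shells: dict[int, list[int]] = {}
        self.proposed = 0
        self.accepted = 0
        self.rejected_clash = 0
        self.rejected_drift = 0
        self.rejected_radius = 0
        self._bases: dict[int, NullspaceBasis] = {}

    @property
    def acceptance_ratio(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0

    def add(self, sample: Sample):
        self.samples.append(sample)
        self.shells.setdefault(sample.shell_index, []).append(sample.id)

    def rmsd_to(self, coords_a: np.ndarray, coords_b: np.ndarray) -> float:
        d = coords_a[self.metric_atoms] - coords_b[self.metric_atoms]
        return float(np.sqrt((d * d).sum() / len(self.metric_atoms)))

    def shell_of(self, rmsd: float) -> int:
        return min(int(rmsd / self.config.shell_width),
                   self.config.n_shells - 1)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample_id": s.id, "parent_id": s.parent_id,
              "shell_index": s.shell_index,
              "rmsd_from_init": s.rmsd_from_init,
              "accepted_step_count": s.accepted_step_count}
             for s in self.samples])

    def q_matrix(self) -> np.ndarray:
        return np.stack([s.q for s in self.samples])

    def save(self, out_dir, topology, ensemble: str = "multi"):
        """Write manifest.csv, torsions.csv (radians) and the ensemble
        (multi-model ensemble.pdb or one numbered PDB per sample)."""
        os.makedirs(out_dir, exist_ok=True)
        write_manifest(self.manifest(), os.path.join(out_dir, "manifest.csv"))
        np.savetxt(os.path.join(out_dir, "torsions.csv"),
                   self.q_matrix(), delimiter=",", fmt="%.9f")
        coords = np.stack([s.coordinates for s in self.samples])
        if ensemble == "multi":
            write_pdb(topology, coords, os.path.join(out_dir, "ensemble.pdb"))
        else:
            for s in self.samples:
                write_pdb(topology, s.coordinates,
                          os.path.join(out_dir, f"sample_{s.id:06d}.pdb"))


def metric_atom_selection(topology) -> np.ndarray:
    """CA atoms (the shell metric); all atoms if the molecule has no CA."""
    ca = topology.ca_indices()
    return ca if len(ca) else np.arange(topology.n_atoms)


def random_conformation(tree: KinematicTree, rng: np.random.Generator) -> Conformation:
    """Entirely random guide conformation: each DoF uniform on [-pi, pi).

    Clashes are deliberately ignored — the guide only steers seed selection
    and is discarded afterwards.
    """
    q = rng.uniform(-np.pi, np.pi, size=tree.n_dofs)
    return Conformation(tree, q)


def select_seed(pool: SamplePool, guide: Conformation,
                rng: np.random.Generator) -> Sample:
    """Pick a uniformly random non-empty shell, then its member closest in
    RMSD to the guide (ties break to the lowest sample id)."""
    occupied = sorted(pool.shells)
    shell = occupied[int(rng.integers(len(occupied)))]
    best_id, best_rmsd = None, np.inf
    for sid in pool.shells[shell]:  # stored in id order -> ties pick lowest
        r = pool.rmsd_to(pool.samples[sid].coordinates, guide.coordinates)
        if r < best_rmsd:
            best_id, best_rmsd = sid, r
    return pool.samples[best_id]


def _basis_at(pool: SamplePool, sample: Sample, cycles) -> NullspaceBasis:
    # J depends on coordinates, so the SVD is recomputed per seed (cached).
    if sample.id not in pool._bases:
        J = compute_jacobian(pool.tree, sample.coordinates, cycles)
        pool._bases[sample.id] = nullspace_basis(J, pool.tree.n_dofs)
    return pool._bases[sample.id]


def propose_step(seed: Sample, basis: NullspaceBasis, pool: SamplePool,
                 constraints, clash_model: ClashModel,
                 rng: np.random.Generator, init_coords: np.ndarray):
    """One projected trial move from ``seed``.

    Draws an isotropic standard-normal trial over all DoFs, projects the
    cycle components onto the constraint tangent space, rescales so the
    largest per-DoF rotation equals ``max_rotation``, and applies forward
    kinematics.  Returns ``(sample, reason)``: on acceptance a new
    :class:`Sample`, otherwise ``reason`` in {'clash', 'drift', 'radius'}.
    """
    cfg = pool.config
    tree = pool.tree
    dq = rng.standard_normal(tree.n_dofs)
    dq = project(dq, basis)
    peak = float(np.abs(dq).max())
    cap = math.radians(cfg.max_rotation)
    if peak > 0.0:
        dq = dq * (cap / peak)
    q_new = seed.q + dq
    coords = forward_kinematics(tree, q_new)
    if detect_clash(coords, clash_model) is not None:
        return None, "clash"
    if constraints and max_drift(constraint_violation(coords, constraints)) > cfg.drift_tolerance:
        return None, "drift"
    rmsd = pool.rmsd_to(coords, init_coords)
    if rmsd > cfg.exploration_radius:
        return None, "radius"
    sample = Sample(id=len(pool.samples), q=q_new, coordinates=coords,
                    parent_id=seed.id, shell_index=pool.shell_of(rmsd),
                    rmsd_from_init=rmsd,
                    accepted_step_count=seed.accepted_step_count + 1)
    return sample, None


MAX_CONSECUTIVE_REJECTIONS = 100_000


def run(tree: KinematicTree, topology, initial_coords: np.ndarray,
        constraints, config: SamplingConfig, log=None) -> SamplePool:
    """Full sampling run: grow the pool to ``config.n_samples`` accepted
    conformations starting from the input structure."""
    from .kinematics import classify_dofs
    from .steric import build_exclusions

    classify_dofs(tree, constraints)
    cycles = find_cycles(tree, constraints)
    excl = build_exclusions(topology, tree, constraints)
    clash_model = ClashModel.from_topology(
        topology, collision_factor=config.collision_factor,
        excluded_pairs=excl)
    pool = SamplePool(tree, config, metric_atom_selection(topology))
    if detect_clash(initial_coords, clash_model) is not None:
        warnings.warn("initial conformation contains clashes")
    pool.add(Sample(id=0, q=np.zeros(tree.n_dofs),
                    coordinates=np.asarray(initial_coords, dtype=float),
                    parent_id=-1, shell_index=0, rmsd_from_init=0.0,
                    accepted_step_count=0))

    rng = np.random.default_rng(config.rng_seed)
    init = pool.samples[0].coordinates
    consecutive_rejects = 0
    accepted = 0
    while accepted < config.n_samples:
        guide = random_conformation(tree, rng)
        seed = select_seed(pool, guide, rng)
        basis = _basis_at(pool, seed, cycles)
        pool.proposed += 1
        sample, reason = propose_step(seed, basis, pool, constraints,
                                      clash_model, rng, init)
        if sample is None:
            consecutive_rejects += 1
            if reason == "clash":
                pool.rejected_clash += 1
            elif reason == "drift":
                pool.rejected_drift += 1
            else:
                pool.rejected_radius += 1
            if consecutive_rejects >= MAX_CONSECUTIVE_REJECTIONS:
                raise RuntimeError(
                    f"no acceptances in {MAX_CONSECUTIVE_REJECTIONS} "
                    f"consecutive proposals (accepted so far: {accepted}; "
                    f"clash {pool.rejected_clash}, drift {pool.rejected_drift}, "
                    f"radius {pool.rejected_radius})")
            continue
        consecutive_rejects = 0
        pool.add(sample)
        pool.accepted += 1
        accepted += 1
        if log is not None and accepted % 100 == 0:
            log(f"accepted {accepted}/{config.n_samples} "
                f"(ratio {pool.acceptance_ratio:.3f}, "
                f"max rmsd {max(s.rmsd_from_init for s in pool.samples):.2f} Å)")
    return pool
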
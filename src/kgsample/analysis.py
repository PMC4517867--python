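"""Ensemble analytics: superposition, domain angles, landscapes,
displacement fields and per-DoF fluctuations.

Angles follow the conventions used for two-domain proteins: the opening
angle is measured between stable-domain-to-mobile-domain center-of-mass
vectors after superposing on the stable domain; zenith/azimuth places the
reference inter-domain axis on +z first; the breathing angle is the plain
angle at the central region's center of mass.  Dihedral fluctuations use
circular statistics so wrap-around at ±180° is handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DomainDefinition",
    "DisplacementField",
    "DofFluctuation",
    "superpose",
    "apply_transform",
    "opening_angle",
    "zenith_azimuth",
    "breathing_angle",
    "landscape_histogram",
    "mean_displacement",
    "displacement_angle_distribution",
    "dof_rmsf",
    "circular_rmsf",
]


@dataclass
class DomainDefinition:
    """A named (possibly discontiguous) residue selection, CA-only default."""

    name: str
    residue_ranges: list            # [(first, last), ...] inclusive
    atom_name: str = "CA"
    chain: str | None = None

    def atom_ids(self, topology) -> np.ndarray:
        ids = [a.id for a in topology.atoms
               if a.name == self.atom_name
               and (self.chain is None or a.chain == self.chain)
               and any(lo <= a.residue_index <= hi
                       for lo, hi in self.residue_ranges)]
        if len(ids) < 3:
            raise ValueError(
                f"domain {self.name!r} resolves to {len(ids)} atoms (< 3)")
        return np.array(ids, dtype=int)


@dataclass
class DisplacementField:
    """Per-residue mean CA displacement vectors of an ensemble."""

    residues: np.ndarray            # residue indices
    vectors: np.ndarray             # (n_res, 3), Å
    normalized: bool = False

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


@dataclass
class DofFluctuation:
    """Per-DoF circular RMSF (degrees) with subset means."""

    rmsf: np.ndarray
    designations: list
    mean_free: float
    mean_cycle: float
    mean_mobile_cycle: float


# ---------------------------------------------------------------------------
# Superposition


def superpose(mobile: np.ndarray, reference: np.ndarray, selection=None):
    """Least-squares rigid superposition (Kabsch) of selected atoms.

    Returns ``(R, t, rmsd)`` with the fitted mobile coordinates given by
    ``x @ R.T + t``; the rotation is proper.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if selection is not None:
        mob_sel, ref_sel = mob[selection], ref[selection]
    else:
        mob_sel, ref_sel = mob, ref
    if mob_sel.shape != ref_sel.shape:
        raise ValueError("selection length mismatch")
    if mob_sel.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mc, rc = mob_sel.mean(axis=0), ref_sel.mean(axis=0)
    a, b = ref_sel - rc, mob_sel - mc
    if np.linalg.matrix_rank(b - b.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = rc - R @ mc
    resid = mob_sel @ R.T + t - ref_sel
    rmsd = float(np.sqrt((resid * resid).sum(axis=1).mean()))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray):
    return np.asarray(coords, float) @ R.T + t


def _com(coords: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return coords[ids].mean(axis=0)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("degenerate center-of-mass geometry")
    c = np.dot(v1, v2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Domain angles


def opening_angle(sample: np.ndarray, reference: np.ndarray,
                  domain_stable: np.ndarray, domain_mobile: np.ndarray) -> float:
    """Inter-domain opening angle Theta in degrees.

    The sample is superposed onto the reference by the stable-domain atoms;
    Theta is the angle between the stable->mobile center-of-mass vectors of
    the reference and of the fitted sample.
    """
    R, t, _ = superpose(sample, reference, domain_stable)
    fitted = apply_transform(sample, R, t)
    v_ref = _com(reference, domain_mobile) - _com(reference, domain_stable)
    v_smp = _com(fitted, domain_mobile) - _com(fitted, domain_stable)
    return _angle_deg(v_ref, v_smp)


def zenith_azimuth(sample: np.ndarray, reference: np.ndarray,
                   domain1: np.ndarray, domain2: np.ndarray):
    """Spherical coordinates (zenith, azimuth; degrees) of the sample's
    domain-2 center of mass.

    The reference is rotated so its domain-1 -> domain-2 center-of-mass axis
    lies on +z, the sample is superposed on reference domain 1, and the
    direction of the sample's COM2 - COM1 is returned as (theta, phi) with
    phi in [0, 360) and phi := 0 when theta < 1e-6 degrees.
    """
    ref = np.asarray(reference, float)
    v = _com(ref, domain2) - _com(ref, domain1)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate reference centers of mass")
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [v / n])
    ref_z = ref @ rot.as_matrix().T
    R, t, _ = superpose(sample, ref_z, domain1)
    fitted = apply_transform(sample, R, t)
    d = _com(fitted, domain2) - _com(fitted, domain1)
    dn = np.linalg.norm(d)
    if dn < 1e-12:
        raise ValueError("degenerate sample centers of mass")
    theta = float(np.degrees(np.arccos(np.clip(d[2] / dn, -1.0, 1.0))))
    if theta < 1e-6:
        return theta, 0.0
    phi = float(np.degrees(np.arctan2(d[1], d[0]))) % 360.0
    return theta, phi


def breathing_angle(coords: np.ndarray, region_a: np.ndarray,
                    region_b: np.ndarray, region_c: np.ndarray) -> float:
    """Angle (degrees) at region b's center of mass between the a and c
    centers of mass."""
    com_a, com_b, com_c = (_com(coords, r) for r in (region_a, region_b, region_c))
    return _angle_deg(com_a - com_b, com_c - com_b)


# ---------------------------------------------------------------------------
# Landscapes


def landscape_histogram(values_x, values_y, bin_x: float = 0.5,
                        bin_y: float = 0.1):
    """2-D histogram on a fixed-width grid plus a -log(frequency) surface.

    Bin edges are aligned to integer multiples of the widths; empty bins are
    masked (NaN) in the -log surface.  Returns
    ``(counts, x_edges, y_edges, neg_log_freq)``.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if bin_x <= 0 or bin_y <= 0:
        raise ValueError("bin widths must be positive")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")

    def edges(v, w):
        lo = np.floor(v.min() / w) * w
        hi = np.ceil(v.max() / w) * w
        if hi <= lo:
            hi = lo + w
        return np.arange(lo, hi + 0.5 * w, w)

    ex, ey = edges(x, bin_x), edges(y, bin_y)
    counts, ex, ey = np.histogram2d(x, y, bins=[ex, ey])
    freq = counts / counts.sum()
    with np.errstate(divide="ignore"):
        neg_log = np.where(counts > 0, -np.log(freq), np.nan)
    return counts, ex, ey, neg_log


# ---------------------------------------------------------------------------
# Displacement fields


def mean_displacement(ensemble, reference: np.ndarray,
                      align_selection: np.ndarray,
                      report_atoms: np.ndarray,
                      report_residues: np.ndarray,
                      normalize: bool = False) -> DisplacementField:
    """Mean per-residue CA displacement of an ensemble from a reference.

    Each sample is superposed on the reference by ``align_selection``; the
    displacement of each reported atom is averaged over samples.  With
    ``normalize=True``, vector magnitudes are scaled by the largest one.
    """
    if len(report_atoms) == 0:
        raise ValueError("empty report selection")
    ref = np.asarray(reference, dtype=float)
    acc = np.zeros((len(report_atoms), 3))
    count = 0
    for coords in ensemble:
        R, t, _ = superpose(coords, ref, align_selection)
        fitted = apply_transform(np.asarray(coords, float), R, t)
        acc += fitted[report_atoms] - ref[report_atoms]
        count += 1
    if count == 0:
        raise ValueError("empty ensemble")
    vectors = acc / count
    if normalize:
        peak = np.linalg.norm(vectors, axis=1).max()
        if peak > 0:
            vectors = vectors / peak
    return DisplacementField(residues=np.asarray(report_residues),
                             vectors=vectors, normalized=normalize)


def displacement_angle_distribution(field_a: DisplacementField,
                                    field_b: DisplacementField,
                                    zero_tol: float = 1e-9):
    """Per-residue angles (degrees) between two mean-displacement fields.

    Residues where either vector is shorter than ``zero_tol`` are excluded;
    returns ``(residues, angles, excluded_residues)``.
    """
    res_a = {int(r): i for i, r in enumerate(field_a.residues)}
    res_b = {int(r): i for i, r in enumerate(field_b.residues)}
    common = sorted(set(res_a) & set(res_b))
    if not common:
        raise ValueError("disjoint residue sets")
    residues, angles, excluded = [], [], []
    for r in common:
        va = field_a.vectors[res_a[r]]
        vb = field_b.vectors[res_b[r]]
        if np.linalg.norm(va) < zero_tol or np.linalg.norm(vb) < zero_tol:
            excluded.append(r)
            continue
        residues.append(r)
        angles.append(_angle_deg(va, vb))
    return np.array(residues), np.array(angles), excluded


# ---------------------------------------------------------------------------
# Dihedral fluctuations


def circular_rmsf(angles_rad: np.ndarray) -> np.ndarray:
    """Wrap-safe RMS fluctuation of angles, in degrees.

    Deviations are measured from the circular mean (direction of the mean
    resultant vector) and wrapped to (-180°, 180°]; for small fluctuations
    this coincides with the linear standard deviation about the mean.
    """
    a = np.asarray(angles_rad, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    mean = np.arctan2(np.sin(a).mean(axis=0), np.cos(a).mean(axis=0))
    dev = np.angle(np.exp(1j * (a - mean)))
    return np.degrees(np.sqrt((dev ** 2).mean(axis=0)))


def dof_rmsf(q_matrix: np.ndarray, designations, rigid_ids=()) -> DofFluctuation:
    """Circular RMSF of every DoF over an ensemble of torsion vectors.

    ``q_matrix`` is (n_samples, n_dofs) in radians; subset means are
    reported for free DoFs, cycle DoFs and non-rigidified ("mobile") cycle
    DoFs.
    """
    q = np.asarray(q_matrix, dtype=float)
    if q.ndim != 2:
        raise ValueError("q_matrix must be (n_samples, n_dofs)")
    if q.shape[0] < 2:
        warnings.warn("single-sample ensemble: all fluctuations are zero")
        rmsf = np.zeros(q.shape[1])
    else:
        rmsf = circular_rmsf(q)
    designations = list(designations)
    rigid = set(rigid_ids)
    free = [i for i, d in enumerate(designations) if d == "free"]
    cyc = [i for i, d in enumerate(designations) if d == "cycle"]
    mobile = [i for i in cyc if i not in rigid]

    def mean_of(idx):
        return float(rmsf[idx].mean()) if idx else 0.0

    return DofFluctuation(rmsf=rmsf, designations=designations,
                          mean_free=mean_of(free), mean_cycle=mean_of(cyc),
                          mean_mobile_cycle=mean_of(mobile))
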
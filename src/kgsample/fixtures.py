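"""Synthetic test molecules with known kinematic and constraint structure.

Three families cover the behaviors the method must exhibit:

* an ideal polyalanine alpha-helix whose i -> i+4 backbone hydrogen bonds
  rigidify the interior backbone,
* a single-cycle serial chain with generic (non-collinear, non-coplanar)
  axes, the minimal system where one closure constraint removes exactly
  five degrees of freedom,
* a two-domain "hinge": two fully constrained helices joined by an
  unconstrained linker, whose opening motion the sampler should find.

All builders are deterministic given their arguments and return
``(Topology, coordinates, constraints, ...)`` ready for the kinematics
pipeline; no input files are required.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .analysis import DomainDefinition
from .geometry import place_atom, unit
from .structure_io import (Atom, HydrogenBond, Topology, infer_bonds,
                           _tag_rotatable)

__all__ = ["make_ideal_helix", "make_single_cycle_chain",
           "make_two_domain_hinge", "write_constraints"]

# Ideal peptide internal coordinates (Å, degrees).
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "N-H": 1.010, "CA-HA": 1.090, "CA-CB": 1.521, "CB-HB": 1.090,
}
_A = {
    "CA-C-N": 116.2, "C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-O": 120.5,
    "C-N-H": 119.15, "N-CA-CB": 110.4, "CA-CB-HB": 109.5,
    "CA-N-H1": 109.5, "N-CA-HA": 108.0,
}
# Improper torsions (a, b, c, new) positioning CA substituents; the signs
# give the L-configuration (verified against the generated geometry).
_TORS_CB = -122.5   # torsion(C, N, CA, CB)
_TORS_HA = 116.0    # torsion(C, N, CA, HA)

HELIX_PHI, HELIX_PSI = -57.0, -47.0
LINKER_PHI, LINKER_PSI = -140.0, 140.0


def _build_polyala(phi_psi):
    """Polyalanine backbone + side groups from per-residue (phi, psi).

    Returns (atoms, coords) with atoms as (name, element, resi) tuples.
    """
    n = len(phi_psi)
    pos: dict[tuple, np.ndarray] = {}
    # seed frame for residue 1
    pos[(1, "N")] = np.array([0.0, 0.0, 0.0])
    pos[(1, "CA")] = np.array([_B["N-CA"], 0.0, 0.0])
    pos[(1, "C")] = place_atom([0.0, -1.0, 0.0], pos[(1, "N")], pos[(1, "CA")],
                               _B["CA-C"], _A["N-CA-C"], 150.0)
    for i in range(2, n + 1):
        phi_prev, psi_prev = phi_psi[i - 2]
        pos[(i, "N")] = place_atom(pos[(i - 1, "N")], pos[(i - 1, "CA")],
                                   pos[(i - 1, "C")], _B["C-N"],
                                   _A["CA-C-N"], psi_prev)
        pos[(i, "CA")] = place_atom(pos[(i - 1, "CA")], pos[(i - 1, "C")],
                                    pos[(i, "N")], _B["N-CA"],
                                    _A["C-N-CA"], 180.0)  # omega fixed, trans
        phi_i = phi_psi[i - 1][0]
        pos[(i, "C")] = place_atom(pos[(i - 1, "C")], pos[(i, "N")],
                                   pos[(i, "CA")], _B["CA-C"],
                                   _A["N-CA-C"], phi_i)
    for i in range(1, n + 1):
        psi_i = phi_psi[i - 1][1]
        pos[(i, "O")] = place_atom(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                                   _B["C-O"], _A["CA-C-O"], psi_i + 180.0)
        if i == 1:
            pos[(i, "H")] = place_atom(pos[(1, "C")], pos[(1, "CA")],
                                       pos[(1, "N")], _B["N-H"],
                                       _A["CA-N-H1"], 180.0)
        else:
            pos[(i, "H")] = place_atom(pos[(i - 1, "O")], pos[(i - 1, "C")],
                                       pos[(i, "N")], _B["N-H"],
                                       _A["C-N-H"], 180.0)
        pos[(i, "CB")] = place_atom(pos[(i, "C")], pos[(i, "N")], pos[(i, "CA")],
                                    _B["CA-CB"], _A["N-CA-CB"], _TORS_CB)
        pos[(i, "HA")] = place_atom(pos[(i, "C")], pos[(i, "N")], pos[(i, "CA")],
                                    _B["CA-HA"], _A["N-CA-HA"], _TORS_HA)
        for k, tors in enumerate((60.0, 180.0, 300.0), start=1):
            pos[(i, f"HB{k}")] = place_atom(pos[(i, "N")], pos[(i, "CA")],
                                            pos[(i, "CB")], _B["CB-HB"],
                                            _A["CA-CB-HB"], tors)

    order = ["N", "H", "CA", "HA", "CB", "HB1", "HB2", "HB3", "C", "O"]
    atoms, coords = [], []
    for i in range(1, n + 1):
        for name in order:
            atoms.append((name, "H" if name.startswith("H") else name[0], i))
            coords.append(pos[(i, name)])
    return atoms, np.asarray(coords)


def _polyala_topology(atoms, coords):
    topo = Topology([Atom(id=k, name=name, element=elem, residue_index=resi,
                          residue_name="ALA", chain="A", serial=k + 1)
                     for k, (name, elem, resi) in enumerate(atoms)])
    infer_bonds(topo, coords)
    return topo


def _helix_constraints(topo, coords, donor_residues):
    """i -> i+4 backbone hydrogen bonds N-H(i+4) ... O=C(i)."""
    out = []
    for i in donor_residues:
        donor = topo.atom_index("A", i + 4, "N")
        hydrogen = topo.atom_index("A", i + 4, "H")
        acceptor = topo.atom_index("A", i, "O")
        out.append(HydrogenBond(
            donor, hydrogen, acceptor,
            float(np.linalg.norm(coords[hydrogen] - coords[acceptor])),
            float(np.linalg.norm(coords[donor] - coords[acceptor]))))
    return out


def make_ideal_helix(n_residues: int = 12):
    """Ideal polyalanine alpha-helix with all i -> i+4 hydrogen bonds.

    phi = -57°, psi = -47°, standard bond geometry, explicit hydrogens.
    Returns ``(Topology, coordinates, constraints)`` with ``n_residues - 4``
    hydrogen bonds.
    """
    if n_residues < 6:
        raise ValueError("need at least 6 residues for an i -> i+4 bond")
    atoms, coords = _build_polyala([(HELIX_PHI, HELIX_PSI)] * n_residues)
    topo = _polyala_topology(atoms, coords)
    constraints = _helix_constraints(topo, coords,
                                     range(1, n_residues - 3))
    return topo, coords, constraints


def make_two_domain_hinge(n_per_domain: int = 8, hinge_len: int = 6):
    """Two fully hydrogen-bonded helices joined by an unconstrained linker.

    Returns ``(Topology, coordinates, constraints, domains)`` where
    ``domains`` is a list of two :class:`DomainDefinition` (CA-only).  Only
    intra-domain i -> i+4 bonds are declared, so the linker torsions stay
    free and the domains can reorient like a hinge.
    """
    if n_per_domain < 6:
        raise ValueError("domains need at least 6 residues")
    if hinge_len < 1:
        raise ValueError("hinge_len must be >= 1")
    n1, nh = n_per_domain, hinge_len
    total = 2 * n_per_domain + nh
    phi_psi = ([(HELIX_PHI, HELIX_PSI)] * n1
               + [(LINKER_PHI, LINKER_PSI)] * nh
               + [(HELIX_PHI, HELIX_PSI)] * n_per_domain)
    atoms, coords = _build_polyala(phi_psi)
    topo = _polyala_topology(atoms, coords)
    donors = [i for i in range(1, total - 3)
              if (i + 4 <= n1) or (i > n1 + nh)]
    constraints = _helix_constraints(topo, coords, donors)
    domains = [
        DomainDefinition("domain1", [(1, n1)]),
        DomainDefinition("domain2", [(n1 + nh + 1, total)]),
    ]
    return topo, coords, constraints, domains


def make_single_cycle_chain(n_cycle_dofs: int = 20, seed: int = 0,
                            bond_length: float = 1.5, gap: float = 3.0,
                            jitter: float = 0.25):
    """Serial chain of single-atom links closed by one hydrogen bond.

    ``n_cycle_dofs + 1`` backbone atoms sit near a circle whose closing gap
    is ``gap`` Å; consecutive atoms are joined by rotatable bonds, the last
    atom carries the donor hydrogen aimed at the first atom (the acceptor),
    and out-of-plane jitter (seeded, deterministic) makes the DoF axes
    generic.  With m = 1 constraint the closure Jacobian has 6 rows and
    generic rank 5.
    """
    if n_cycle_dofs < 6:
        raise ValueError("need at least 6 cycle DoFs")
    n = n_cycle_dofs
    ratio = gap / bond_length

    def h(delta):
        return np.sin(n * delta / 2.0) - ratio * np.sin(delta / 2.0)

    delta = brentq(h, 1e-4, 2.0 * np.pi / n - 1e-9)
    radius = bond_length / (2.0 * np.sin(delta / 2.0))

    rng = np.random.default_rng(seed)
    pts = []
    for k in range(n + 1):
        theta = k * delta
        p = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        if 0 < k < n:  # keep the two gap endpoints exact
            p += rng.uniform(-jitter, jitter, 3) * np.array([0.2, 0.2, 1.0])
        pts.append(p)
    pts = np.array(pts)

    hydrogen_pos = pts[n] + unit(pts[0] - pts[n]) * 1.0
    anchor_pos = pts[0] + unit(pts[0]) * 1.4

    atoms, coords = [], []

    def add(name, element, p):
        atoms.append(Atom(id=len(atoms), name=name, element=element,
                          residue_index=1, residue_name="CHN", chain="A",
                          serial=len(atoms) + 1))
        coords.append(p)

    add("X0", "C", anchor_pos)
    add("O1", "O", pts[0])                       # acceptor
    for k in range(1, n):
        add(f"C{k + 1}", "C", pts[k])
    add(f"N{n + 1}", "N", pts[n])                # donor heavy atom
    add("H1", "H", hydrogen_pos)
    coords = np.asarray(coords)

    topo = Topology(atoms)
    topo.add_bond(0, 1)                          # anchor, fixed by rules
    for k in range(1, n + 1):
        topo.add_bond(k, k + 1)
    topo.add_bond(n + 1, n + 2)                  # donor-H
    _tag_rotatable(topo)

    donor, hydrogen, acceptor = n + 1, n + 2, 1
    constraints = [HydrogenBond(
        donor, hydrogen, acceptor,
        float(np.linalg.norm(coords[hydrogen] - coords[acceptor])),
        float(np.linalg.norm(coords[donor] - coords[acceptor])))]
    return topo, coords, constraints


def write_constraints(path, topology, constraints):
    """Write constraints in the plain-text format parse_constraints reads."""
    lines = ["# chain resi donor hydrogen acceptor_chain acceptor_resi acceptor"]
    for hb in constraints:
        d = topology.atoms[hb.donor]
        h = topology.atoms[hb.hydrogen]
        a = topology.atoms[hb.acceptor]
        lines.append(f"{d.chain} {d.residue_index} {d.name} {h.name} "
                     f"{a.chain} {a.residue_index} {a.name}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
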
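"""Protein structure input/output and hydrogen-bond constraint parsing.

Reads all-atom PDB files (explicit hydrogens expected) into a light-weight
:class:`Topology` plus a coordinate snapshot, infers covalent bonds from
residue templates (CONECT records for everything else), tags each bond
rotatable or fixed according to the kinematic rules, and parses the
plain-text hydrogen-bond constraint file that drives the closure
constraints.

Constraint file format (one bond per line, ``#`` comments allowed)::

    chain resi donor_name hydrogen_name acceptor_chain acceptor_resi acceptor_name
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "HydrogenBond",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "infer_bonds",
    "parse_constraints",
    "disulfide_constraints",
    "read_manifest",
    "write_manifest",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

# Heavy-atom side-chain connectivity of the 20 standard amino acids.
_SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

# Atoms belonging to rings; bonds with both endpoints in the set never rotate.
_RING_ATOMS = {
    "PRO": {"N", "CA", "CB", "CG", "CD"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}

# Partial double bonds (planar groups) that are kinematically fixed.
_PLANAR_BONDS = {
    "ASP": {frozenset(p) for p in [("CG", "OD1"), ("CG", "OD2")]},
    "GLU": {frozenset(p) for p in [("CD", "OE1"), ("CD", "OE2")]},
    "ASN": {frozenset(p) for p in [("CG", "OD1"), ("CG", "ND2")]},
    "GLN": {frozenset(p) for p in [("CD", "OE1"), ("CD", "NE2")]},
    "ARG": {frozenset(p) for p in [("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")]},
}

_H_ATTACH_CUTOFF = 1.3  # Å; covalent X-H bonds are 0.95-1.1 Å


class StructureError(ValueError):
    """Raised for malformed structures or constraint files."""


@dataclass(frozen=True)
class Atom:
    """One atom of the model. ``id`` is the index into the topology order."""

    id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    serial: int = 0

    @property
    def key(self):
        return (self.chain, self.residue_index, self.name)


@dataclass
class HydrogenBond:
    """A cycle-closing hydrogen bond used as a distance constraint.

    The donor is the heavy atom, ``hydrogen`` its covalently bound H, and the
    constraint preserves both the H···acceptor and donor···acceptor distances
    recorded at load time.
    """

    donor: int
    hydrogen: int
    acceptor: int
    initial_distance_HA: float
    initial_distance_DA: float


class Topology:
    """Atoms plus a covalent bond graph with rotatable flags."""

    def __init__(self, atoms, bonds=None, disulfides=None):
        self.atoms: list[Atom] = list(atoms)
        # (i, j) with i < j  ->  rotatable flag
        self.bonds: dict[tuple[int, int], bool] = dict(bonds or {})
        self.disulfides: list[tuple[int, int]] = list(disulfides or [])
        self._check_unique_keys()
        self._adjacency = None

    # -- bookkeeping ------------------------------------------------------
    def _check_unique_keys(self):
        seen = {}
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(
                    f"ambiguous atom: {a.key} appears more than once")
            seen[a.key] = a.id

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self):
        """Ordered (chain, residue_index, residue_name) records."""
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain, a.residue_index, a.residue_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom_index(self, chain: str, residue_index: int, name: str) -> int:
        if not hasattr(self, "_index"):
            self._index = {a.key: a.id for a in self.atoms}
        key = (chain, residue_index, name)
        if key not in self._index:
            raise KeyError(f"no atom {key}")
        return self._index[key]

    def add_bond(self, i: int, j: int, rotatable: bool = False):
        if i == j:
            raise StructureError(f"self-bond on atom {i}")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise StructureError(f"bond endpoint out of range: ({i}, {j})")
        self.bonds[(min(i, j), max(i, j))] = rotatable
        self._adjacency = None

    def adjacency(self) -> list[list[int]]:
        if self._adjacency is None:
            adj = [[] for _ in range(self.n_atoms)]
            for (i, j) in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adjacency = [sorted(n) for n in adj]
        return self._adjacency

    def bonded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds

    def select(self, predicate) -> np.ndarray:
        """Atom ids for which ``predicate(atom)`` holds."""
        return np.array([a.id for a in self.atoms if predicate(a)], dtype=int)

    def ca_indices(self) -> np.ndarray:
        return self.select(lambda a: a.name == "CA")


# ---------------------------------------------------------------------------
# Reading


def read_pdb(path, require_hydrogens: bool = False, include_hetero=(),
             infer: bool = True):
    """Read a PDB file into ``(Topology, coordinates)``.

    Keeps the first model only; alternate locations are resolved to the
    highest-occupancy conformer (first wins ties).  Waters and HETATM
    residues are dropped unless named in ``include_hetero``.  Covalent bonds
    are inferred from residue templates and CONECT records unless
    ``infer=False``.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise StructureError("empty structure: no models")
    model = st[0]
    include_hetero = set(include_hetero)

    records = []  # (chain, resi, resname, name, element, serial, pos, occ)
    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname in WATER_NAMES:
                continue
            if res.het_flag == "H" and rname not in STANDARD_RESIDUES \
                    and rname not in include_hetero:
                continue
            best = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:
                if best[at.name] is not at:
                    continue
                records.append((chain.name, res.seqid.num, rname, at.name,
                                at.element.name.upper(), at.serial,
                                (at.pos.x, at.pos.y, at.pos.z)))
    if not records:
        raise StructureError("empty structure")

    atoms, coords, serial_to_id = [], [], {}
    for idx, (ch, resi, rname, name, elem, serial, pos) in enumerate(records):
        atoms.append(Atom(id=idx, name=name, element=elem or name[0],
                          residue_index=resi, residue_name=rname,
                          chain=ch, serial=serial))
        serial_to_id[serial] = idx
        coords.append(pos)
    topo = Topology(atoms)
    coords = np.asarray(coords, dtype=float)

    if require_hydrogens:
        by_res = {}
        for a in atoms:
            if a.residue_name in STANDARD_RESIDUES:
                by_res.setdefault((a.chain, a.residue_index), []).append(a)
        for key, res_atoms in by_res.items():
            if not any(a.element == "H" for a in res_atoms):
                raise StructureError(
                    f"hydrogens missing: residue {key} has no H atoms")

    conect = _parse_conect(path, serial_to_id)
    if infer:
        infer_bonds(topo, coords, conect_pairs=conect)
    return topo, coords


def read_ensemble(path, **kwargs):
    """Read a multi-model PDB into ``(Topology, coordinates (k, n, 3))``.

    The topology is taken from the first model; every model must have the
    same atoms in the same order.
    """
    topo, first = read_pdb(path, **kwargs)
    st = gemmi.read_pdb(str(path))
    frames = []
    for model in st:
        xyz = []
        for chain in model:
            for res in chain:
                if res.name.strip() in WATER_NAMES:
                    continue
                if res.het_flag == "H" and res.name.strip() not in STANDARD_RESIDUES \
                        and res.name.strip() not in set(kwargs.get("include_hetero", ())):
                    continue
                for at in res:
                    xyz.append((at.pos.x, at.pos.y, at.pos.z))
        frame = np.asarray(xyz, dtype=float)
        if frame.shape != first.shape:
            raise StructureError("models differ in atom count")
        frames.append(frame)
    return topo, np.stack(frames)


def _parse_conect(path, serial_to_id):
    pairs = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = [line[6:11], line[11:16], line[16:21], line[21:26], line[26:31]]
            nums = [int(f) for f in fields if f.strip()]
            if not nums:
                continue
            a = nums[0]
            for b in nums[1:]:
                if a in serial_to_id and b in serial_to_id:
                    i, j = serial_to_id[a], serial_to_id[b]
                    if i != j:
                        pairs.add((min(i, j), max(i, j)))
    return pairs


# ---------------------------------------------------------------------------
# Bond inference and rotatability rules


def infer_bonds(topology: Topology, coords: np.ndarray, conect_pairs=()):
    """Populate ``topology.bonds`` from residue templates and CONECT pairs.

    Heavy-atom connectivity of standard residues comes from templates;
    hydrogens attach to the nearest heavy atom of their residue; consecutive
    residues of a chain get the peptide C-N bond.  Every bond is then tagged
    rotatable or fixed.  Idempotent: bonds are rebuilt from scratch.
    """
    topology.bonds = {}
    topology._adjacency = None
    atoms = topology.atoms
    by_res: dict[tuple, dict[str, Atom]] = {}
    res_order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.residue_index, a.residue_name)
        if key not in by_res:
            by_res[key] = {}
            res_order.append(key)
        by_res[key][a.name] = a

    conect_touch = set()
    for (i, j) in conect_pairs:
        conect_touch.add(atoms[i].key[:2] + (atoms[i].residue_name,))
        conect_touch.add(atoms[j].key[:2] + (atoms[j].residue_name,))

    for key in res_order:
        ch, resi, rname = key
        names = by_res[key]
        if rname in STANDARD_RESIDUES:
            pairs = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
            pairs += _SIDECHAIN_BONDS[rname]
            for a_name, b_name in pairs:
                if a_name in names and b_name in names:
                    topology.add_bond(names[a_name].id, names[b_name].id)
            # hydrogens: nearest heavy atom in the residue
            heavies = [a for a in names.values() if a.element != "H"]
            for a in names.values():
                if a.element != "H":
                    continue
                dists = [(np.linalg.norm(coords[a.id] - coords[h.id]), h.id)
                         for h in heavies]
                d, hid = min(dists)
                if d > _H_ATTACH_CUTOFF:
                    raise StructureError(
                        f"hydrogen {a.key} has no heavy atom within "
                        f"{_H_ATTACH_CUTOFF} Å")
                topology.add_bond(a.id, hid)
        elif key not in conect_touch:
            raise StructureError(
                f"unbondable residue {key}: not a standard amino acid and "
                "no CONECT records")

    # peptide bonds between consecutive residue numbers of each chain
    # (independent of atom order in the file; a distance sanity check keeps
    # numbering gaps across chain breaks unbonded)
    loc = {(ch, resi): key for key in res_order
           for (ch, resi, rname) in [key] if rname in STANDARD_RESIDUES}
    for (ch, resi), prev in loc.items():
        cur = loc.get((ch, resi + 1))
        if cur is None:
            continue
        if "C" in by_res[prev] and "N" in by_res[cur]:
            c, n = by_res[prev]["C"].id, by_res[cur]["N"].id
            if np.linalg.norm(coords[c] - coords[n]) < 2.0:
                topology.add_bond(c, n)

    for (i, j) in conect_pairs:
        topology.add_bond(i, j)

    # disulfides close covalent cycles; break them out of the bond graph
    topology.disulfides = []
    for (i, j) in list(topology.bonds):
        ai, aj = atoms[i], atoms[j]
        if ai.name == "SG" and aj.name == "SG" and ai.residue_name == "CYS" \
                and aj.residue_name == "CYS":
            del topology.bonds[(i, j)]
            topology.disulfides.append((i, j))
    topology._adjacency = None

    _tag_rotatable(topology)
    return topology


def _tag_rotatable(topology: Topology):
    atoms = topology.atoms
    adj = topology.adjacency()

    def is_methyl_like(c: int) -> bool:
        # carbon whose only other neighbors are exactly three hydrogens
        if atoms[c].element != "C":
            return False
        hs = [n for n in adj[c] if atoms[n].element == "H"]
        return len(hs) == 3 and len(adj[c]) == 4

    for (i, j) in list(topology.bonds):
        ai, aj = atoms[i], atoms[j]
        rot = True
        if ai.element == "H" or aj.element == "H":
            rot = False
        elif len(adj[i]) == 1 or len(adj[j]) == 1:
            rot = False  # rotation about a terminal bond moves nothing
        elif {ai.name, aj.name} == {"C", "N"} and ai.residue_index != aj.residue_index:
            rot = False  # peptide omega
        elif ai.residue_index == aj.residue_index and ai.residue_name == aj.residue_name:
            rname = ai.residue_name
            ring = _RING_ATOMS.get(rname, set())
            planar = _PLANAR_BONDS.get(rname, set())
            if ai.name in ring and aj.name in ring:
                rot = False
            elif frozenset((ai.name, aj.name)) in planar:
                rot = False
            elif "O" in (ai.name, aj.name) or "OXT" in (ai.name, aj.name):
                if "C" in (ai.name, aj.name):
                    rot = False  # backbone carbonyl / carboxylate
        if rot and (is_methyl_like(i) or is_methyl_like(j)):
            rot = False  # symmetric CH3 rotor: excluded by default
        topology.bonds[(i, j)] = rot


# ---------------------------------------------------------------------------
# Writing


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(topology: Topology, coordinates, path, conect: str = "auto"):
    """Write ``coordinates`` (one conformation, (n,3), or a sequence of
    conformations written as MODEL blocks) as a PDB file.

    ``conect='auto'`` emits CONECT records when any residue is non-standard;
    'always'/'never' force the behavior.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 2:
        frames = coords[None, :, :]
    elif coords.ndim == 3:
        frames = coords
    else:
        raise StructureError("coordinates must be (n,3) or (k,n,3)")
    if frames.shape[1] != topology.n_atoms or frames.shape[2] != 3:
        raise StructureError(
            f"coordinate/atom count mismatch: {frames.shape[1]} vs "
            f"{topology.n_atoms} atoms")
    if not np.isfinite(frames).all():
        raise StructureError("non-finite coordinate; refusing to write")

    multi = frames.shape[0] > 1
    nonstandard = any(a.residue_name not in STANDARD_RESIDUES
                      for a in topology.atoms)
    emit_conect = conect == "always" or (conect == "auto" and nonstandard)

    lines = []
    for k, frame in enumerate(frames):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        for a in topology.atoms:
            x, y, z = frame[a.id]
            # ATOM for everything we write: our synthetic residues are part
            # of the covalent model, not ligands
            lines.append(
                f"{'ATOM':<6s}{a.id + 1:5d} {_format_atom_name(a.name, a.element)}"
                f" {a.residue_name:>3s} {a.chain[:1]:1s}{a.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}")
        if multi:
            lines.append("ENDMDL")
    if emit_conect:
        for (i, j) in sorted(set(topology.bonds) | set(topology.disulfides)):
            lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Constraints


def parse_constraints(path, topology: Topology, coordinates) -> list[HydrogenBond]:
    """Parse the hydrogen-bond constraint file against a topology.

    Returns one :class:`HydrogenBond` per unique (donor, hydrogen, acceptor)
    triple, with initial distances measured on ``coordinates``.
    """
    coords = np.asarray(coordinates, dtype=float)
    bonds, seen = [], set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise StructureError(
                    f"constraint line {lineno}: expected 7 fields, got "
                    f"{len(fields)}")
            ch, resi, dname, hname, ach, aresi, aname = fields
            try:
                donor = topology.atom_index(ch, int(resi), dname)
                hydrogen = topology.atom_index(ch, int(resi), hname)
                acceptor = topology.atom_index(ach, int(aresi), aname)
            except KeyError as exc:
                raise StructureError(
                    f"constraint line {lineno}: {exc.args[0]}") from exc
            if not topology.bonded(donor, hydrogen):
                raise StructureError(
                    f"constraint line {lineno}: hydrogen {hname} not "
                    f"covalently bonded to donor {dname}")
            if topology.bonded(donor, acceptor):
                raise StructureError(
                    f"constraint line {lineno}: acceptor covalently bonded "
                    "to donor")
            triple = (donor, hydrogen, acceptor)
            if triple in seen:
                continue
            seen.add(triple)
            d_ha = float(np.linalg.norm(coords[hydrogen] - coords[acceptor]))
            d_da = float(np.linalg.norm(coords[donor] - coords[acceptor]))
            if d_ha <= 0 or d_da <= 0:
                raise StructureError(
                    f"constraint line {lineno}: degenerate geometry")
            bonds.append(HydrogenBond(donor, hydrogen, acceptor, d_ha, d_da))
    return bonds


def disulfide_constraints(topology: Topology, coordinates) -> list[HydrogenBond]:
    """Closure constraints for recorded SG-SG disulfides.

    Each disulfide is expressed in the same 6-row form as a hydrogen bond:
    the CB of the first cysteine plays the donor, its SG the 'hydrogen'
    (the constrained atom on the left branch), the partner SG the acceptor.
    """
    coords = np.asarray(coordinates, dtype=float)
    out = []
    for (i, j) in topology.disulfides:
        sg1, sg2 = topology.atoms[i], topology.atoms[j]
        cb = topology.atom_index(sg1.chain, sg1.residue_index, "CB")
        d_ha = float(np.linalg.norm(coords[i] - coords[j]))
        d_da = float(np.linalg.norm(coords[cb] - coords[j]))
        out.append(HydrogenBond(cb, i, j, d_ha, d_da))
    return out


# ---------------------------------------------------------------------------
# Ensemble manifests


def write_manifest(frame, path):
    """Write a sample manifest (pandas DataFrame) with stable formatting."""
    frame.to_csv(path, index=False, float_format="%.6f")


def read_manifest(path):
    import pandas as pd

    return pd.read_csv(path)
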
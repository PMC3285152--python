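"""Build a constraint topology from a PDB/mmCIF protein structure.

Every heavy atom (plus polar hydrogens, when present) becomes a 6-DOF rigid
body.  Covalent bonds within a residue are 5-bar constraints (one DOF left
for the dihedral); peptide C–N bonds are 6-bar linkers (the amide's partial
double bond locks rotation); disulfides are 5-bar; geometrically detected
hydrogen bonds and salt bridges are fluctuating 3-bar constraints.  Backbone
N–CA and CA–C bonds are flagged rotatable — the phi/psi torsion set — except
at chain termini and for the proline ring-locked phi.

Covalent connectivity comes from a residue template table, with a 1.9 A
heavy-atom distance fallback for nonstandard residues and ligands.  Hydrogen
bond identification is purely geometric (donor–acceptor distance, plus a
D–H···A angle screen when hydrogens are present); no energy function is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .network import Constraint, ConstraintTopology, VertexMeta

__all__ = ["HbondGeometry", "build_ctf", "enumerate_torsions"]


@dataclass
class HbondGeometry:
    """Geometric hydrogen-bond criteria.

    ``max_da_distance``: donor–acceptor distance ceiling in Angstrom
    (conventional 3.5); ``min_dha_angle``: D–H···A angle floor in degrees
    (conventional 120), applied only when the donor carries a hydrogen;
    ``max_salt_bridge``: carboxylate-O to basic-N ceiling for salt bridges,
    which are treated as a special kind of hydrogen bond.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0
    max_salt_bridge: float = 4.0

    def validate(self) -> None:
        # zero disables the corresponding detection entirely
        if self.max_da_distance < 0 or self.max_salt_bridge < 0:
            raise ValueError("distances must be non-negative")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle must be in (0, 180]")


_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
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

# donor atoms (N/O/S that can donate a proton) and acceptors, by atom name;
# backbone N donates and backbone O/OXT accept in every residue.
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"},
}
_ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
            ("HIS", "ND1"), ("HIS", "NE2")}

_COVALENT_FALLBACK = 1.9  # heavy-atom bond ceiling, Angstrom
_SS_BOND_MAX = 2.5        # S-gamma pair ceiling for disulfides


class _Atom:
    __slots__ = ("vid", "name", "element", "pos", "chain", "resseq",
                 "resname", "is_standard", "is_hydrogen")

    def __init__(self, vid, name, element, pos, chain, resseq, resname,
                 is_standard, is_hydrogen):
        self.vid = vid
        self.name = name
        self.element = element
        self.pos = pos
        self.chain = chain
        self.resseq = resseq
        self.resname = resname
        self.is_standard = is_standard
        self.is_hydrogen = is_hydrogen


def build_ctf(structure, hbond_geometry: HbondGeometry | None = None,
              include_ligands: bool = False) -> ConstraintTopology:
    """Convert a protein structure into a :class:`ConstraintTopology`.

    ``structure`` is a path to a PDB/mmCIF file or a ``gemmi.Structure``.
    Only the first model is used; alternate conformations are reduced to the
    highest-occupancy one; waters are always excluded and other heteroatoms
    only included with ``include_ligands``.  Hydrogen bonds get occupancy 1
    in the returned topology — dilution is applied downstream.
    """
    geom = hbond_geometry or HbondGeometry()
    geom.validate()
    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    structure.remove_alternative_conformations()
    structure.remove_empty_chains()
    model = structure[0]

    atoms: list[_Atom] = []
    residues: list[dict] = []  # per residue: name->atom, chain, seq, resname
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_water = info is not None and info.is_water()
            if is_water:
                continue
            is_aa = res.name in _SIDECHAIN_BONDS
            if not is_aa and not include_ligands:
                continue
            res_atoms: dict[str, _Atom] = {}
            for at in res:
                elem = at.element.name.upper()
                is_h = elem in ("H", "D")
                if is_h and not _is_polar_hydrogen(at, res):
                    continue
                a = _Atom(len(atoms), at.name, elem,
                          np.array([at.pos.x, at.pos.y, at.pos.z]),
                          chain.name, res.seqid.num, res.name, is_aa, is_h)
                atoms.append(a)
                res_atoms[at.name] = a
            if res_atoms:
                residues.append({"atoms": res_atoms, "chain": chain.name,
                                 "seq": res.seqid.num, "name": res.name})

    if not atoms:
        raise ValueError("structure contains no usable atoms")

    constraints: list[Constraint] = []
    seen_pairs: set[tuple[int, int]] = set()

    def add(u, v, kind, bars, prob=1.0, rotatable=False):
        key = (min(u, v), max(u, v))
        if key in seen_pairs and kind != "hbond":
            return
        seen_pairs.add(key)
        constraints.append(Constraint(u, v, kind, bars, prob, rotatable))

    # covalent bonds within residues (template, then distance fallback)
    for res in residues:
        ra = res["atoms"]
        if res["name"] in _SIDECHAIN_BONDS:
            bonds = _BACKBONE_BONDS + _SIDECHAIN_BONDS[res["name"]]
            for a_name, b_name in bonds:
                if a_name in ra and b_name in ra:
                    add(ra[a_name].vid, ra[b_name].vid, "intra_residue", 5)
        else:
            _distance_bonds(list(ra.values()), add)
        # polar hydrogens bond to their nearest heavy atom
        for a in ra.values():
            if a.is_hydrogen:
                parent = min(
                    (b for b in ra.values() if not b.is_hydrogen),
                    key=lambda b: np.linalg.norm(a.pos - b.pos),
                    default=None,
                )
                if parent is not None:
                    add(a.vid, parent.vid, "intra_residue", 5)

    # peptide linkers between consecutive residues of the same chain
    for prev, cur in zip(residues, residues[1:]):
        if prev["chain"] != cur["chain"]:
            continue
        c_at, n_at = prev["atoms"].get("C"), cur["atoms"].get("N")
        if c_at is None or n_at is None:
            warnings.warn(
                f"missing backbone atoms between {prev['chain']}{prev['seq']} "
                f"and {cur['chain']}{cur['seq']}; peptide link skipped"
            )
            continue
        if np.linalg.norm(c_at.pos - n_at.pos) <= _COVALENT_FALLBACK:
            add(c_at.vid, n_at.vid, "linker", 6)
        else:
            warnings.warn(
                f"chain break between {prev['chain']}{prev['seq']} and "
                f"{cur['chain']}{cur['seq']}"
            )

    # disulfides
    sg = [a for a in atoms if a.name == "SG" and a.resname == "CYS"]
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i].pos - sg[j].pos) <= _SS_BOND_MAX:
                add(sg[i].vid, sg[j].vid, "disulfide", 5)

    _detect_hbonds(atoms, geom, seen_pairs, constraints)

    # assemble metadata and rotatable flags
    meta = {
        a.vid: VertexMeta(
            label=f"{a.chain}:{a.resseq}:{a.name}",
            calpha=(a.name == "CA" and a.is_standard),
            chain=a.chain, residue=a.resseq, atom=a.name,
        )
        for a in atoms
    }
    _flag_torsions(residues, constraints)
    topo = ConstraintTopology(len(atoms), constraints, meta)
    topo.validate()
    return topo


def _is_polar_hydrogen(at, res) -> bool:
    # polar hydrogens sit within covalent range of N/O/S
    for other in res:
        if other.element.name in ("N", "O", "S"):
            if at.pos.dist(other.pos) <= 1.2:
                return True
    return False


def _distance_bonds(res_atoms, add) -> None:
    heavy = [a for a in res_atoms if not a.is_hydrogen]
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            if np.linalg.norm(heavy[i].pos - heavy[j].pos) <= _COVALENT_FALLBACK:
                add(heavy[i].vid, heavy[j].vid, "intra_residue", 5)


def _detect_hbonds(atoms, geom, covalent_pairs, constraints) -> None:
    donors, acceptors, hydrogens = [], [], {}
    for a in atoms:
        if a.is_hydrogen:
            continue
        if a.is_standard:
            if a.name == "N" or a.name in _SIDECHAIN_DONORS.get(a.resname, ()):
                donors.append(a)
            if a.name in ("O", "OXT") or a.name in _SIDECHAIN_ACCEPTORS.get(
                    a.resname, ()):
                acceptors.append(a)
        elif a.element in ("N", "O"):
            donors.append(a)
            acceptors.append(a)
    for h in atoms:
        if h.is_hydrogen:
            parent = min(
                (b for b in atoms if not b.is_hydrogen
                 and b.chain == h.chain and b.resseq == h.resseq),
                key=lambda b: np.linalg.norm(h.pos - b.pos), default=None)
            if parent is not None:
                hydrogens.setdefault(parent.vid, []).append(h)

    if not donors or not acceptors:
        return
    acc_tree = cKDTree(np.array([a.pos for a in acceptors]))
    cutoff = max(geom.max_da_distance, geom.max_salt_bridge)
    added: set[tuple[int, int]] = set()
    for d in donors:
        for j in acc_tree.query_ball_point(d.pos, cutoff):
            a = acceptors[j]
            if a.vid == d.vid:
                continue
            key = (min(d.vid, a.vid), max(d.vid, a.vid))
            if key in added or key in covalent_pairs:
                continue
            # skip pairs in the same or adjacent residues: covalently close
            if d.chain == a.chain and abs(d.resseq - a.resseq) < 2:
                continue
            dist = np.linalg.norm(d.pos - a.pos)
            is_salt = ((a.resname, a.name) in _ACIDIC_O
                       and (d.resname, d.name) in _BASIC_N
                       and dist <= geom.max_salt_bridge)
            is_hb = dist <= geom.max_da_distance
            if is_hb and d.vid in hydrogens:
                is_hb = any(
                    _dha_angle(d.pos, h.pos, a.pos) >= geom.min_dha_angle
                    for h in hydrogens[d.vid]
                )
            if is_hb or is_salt:
                added.add(key)
                constraints.append(Constraint(key[0], key[1], "hbond", 3, 1.0))


def _dha_angle(d_pos, h_pos, a_pos) -> float:
    # donor-hydrogen...acceptor angle, at the hydrogen
    u = d_pos - h_pos
    w = a_pos - h_pos
    cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _flag_torsions(residues, constraints) -> None:
    """Mark backbone N-CA (phi) and CA-C (psi) bonds rotatable.

    Phi is absent at a chain's first residue and for proline (ring closure);
    psi is absent at a chain's last residue.
    """
    by_chain: dict[str, list[dict]] = {}
    for res in residues:
        if res["name"] in _SIDECHAIN_BONDS:
            by_chain.setdefault(res["chain"], []).append(res)
    rotatable_pairs: set[tuple[int, int]] = set()
    for chain_residues in by_chain.values():
        for pos, res in enumerate(chain_residues):
            ra = res["atoms"]
            if "N" in ra and "CA" in ra and pos > 0 and res["name"] != "PRO":
                u, v = ra["N"].vid, ra["CA"].vid
                rotatable_pairs.add((min(u, v), max(u, v)))
            if "CA" in ra and "C" in ra and pos < len(chain_residues) - 1:
                u, v = ra["CA"].vid, ra["C"].vid
                rotatable_pairs.add((min(u, v), max(u, v)))
    for i, c in enumerate(constraints):
        if c.kind == "intra_residue" and (min(c.u, c.v), max(c.u, c.v)) in \
                rotatable_pairs:
            constraints[i] = Constraint(c.u, c.v, c.kind, c.bars, c.prob,
                                        rotatable=True)


def enumerate_torsions(topology: ConstraintTopology) -> list[tuple[int, int]]:
    """Rotatable backbone bonds (phi/psi torsions) in constraint order."""
    return [(c.u, c.v) for c in topology.rotatable_constraints]
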
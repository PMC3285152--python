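"""Deterministic generators for toy and protein-like constraint networks.

Everything every other module needs for testing and demonstration is built
here programmatically: the worked three-vertex triangle, globally rigid
chains, a small two-hydrogen-bond toy network, random protein-like chains,
and small synthetic PDB files for exercising the structure reader.
"""

from __future__ import annotations

import numpy as np

from .network import Constraint, ConstraintTopology, VertexMeta, WeightedNetwork

__all__ = [
    "triangle_network",
    "fully_rigid_network",
    "toy_two_hbond_network",
    "chain_protein",
    "write_synthetic_dipeptide_pdb",
    "write_synthetic_helix_pdb",
]


def triangle_network() -> WeightedNetwork:
    """Three 6-DOF bodies joined pairwise by edges of capacity 0.6, 5, 5.

    The canonical worked example for the fractional game: all three edges are
    independent, the run leaves 7.4 free DOF (1.4 beyond the 6 trivial ones),
    and the rigid cluster decomposition yields three singletons.
    """
    return WeightedNetwork(3, [(0, 1, 0.6), (0, 2, 5.0), (1, 2, 5.0)])


def fully_rigid_network(n: int) -> WeightedNetwork:
    """A chain of ``n`` bodies linked by 6-bar edges: exactly 6 DOF remain.

    Every edge locks all relative motion of its pair, so the whole chain is
    one rigid cluster with only the trivial rigid-body DOF left.
    """
    if n < 1:
        raise ValueError("need at least one vertex")
    return WeightedNetwork(n, [(i, i + 1, 6.0) for i in range(n - 1)])


def toy_two_hbond_network() -> ConstraintTopology:
    """An 8-vertex quenched backbone cross-linked by two hydrogen bonds.

    The covalent path alternates 5-bar (rotatable) and 6-bar edges; the two
    fluctuating hydrogen bonds, (0,5) and (2,7), generate an ensemble of
    exactly four integer networks.  This is the canonical small fixture for
    checking Monte-Carlo sampling against exact enumeration.
    """
    constraints = []
    for i in range(7):
        if i % 2 == 0:
            constraints.append(Constraint(i, i + 1, "intra_residue", 5,
                                          rotatable=True))
        else:
            constraints.append(Constraint(i, i + 1, "linker", 6))
    constraints.append(Constraint(0, 5, "hbond", 3, prob=0.5))
    constraints.append(Constraint(2, 7, "hbond", 3, prob=0.5))
    meta = {i: VertexMeta(label=f"v{i}") for i in range(8)}
    return ConstraintTopology(8, constraints, meta)


def chain_protein(n_residues: int, hbonds_per_residue: float, seed: int,
                  sep_decay: float = 0.35) -> ConstraintTopology:
    """Random protein-like chain: 3 bodies per residue plus cross-links.

    Each residue contributes N, CA and C bodies joined by 5-bar rotatable
    bonds (the phi/psi torsions); consecutive residues are joined by 6-bar
    peptide linkers.  The two chain-terminal bonds are modeled as 6-bar
    locked edges (standing in for the extra terminal atoms of a real chain),
    which makes the cross-link-free chain's excess DOF equal its torsion
    count, ``2 n_residues - 2``.

    Cross-links are 3-bar hydrogen bonds between alpha carbons of residues
    at least 3 apart; their number is Poisson with mean
    ``hbonds_per_residue * n_residues`` and their sequence separation is
    ``3 + Geometric(sep_decay) - 1``, mimicking the short-range-dominated
    contact maps of real proteins (secondary-structure-like local contacts
    rigidify the chain progressively, which is what gives the dilution
    sweep its susceptibility peak).  Deterministic under ``seed``.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    if not 0 < sep_decay <= 1:
        raise ValueError("sep_decay must be in (0, 1]")
    rng = np.random.default_rng(seed)
    constraints: list[Constraint] = []
    meta: dict[int, VertexMeta] = {}
    for i in range(n_residues):
        n_id, ca_id, c_id = 3 * i, 3 * i + 1, 3 * i + 2
        meta[n_id] = VertexMeta(label=f"N{i}", residue=i, atom="N")
        meta[ca_id] = VertexMeta(label=f"CA{i}", calpha=True, residue=i,
                                 atom="CA")
        meta[c_id] = VertexMeta(label=f"C{i}", residue=i, atom="C")
        if i == 0:  # locked N-terminal bond
            constraints.append(Constraint(n_id, ca_id, "linker", 6))
        else:
            constraints.append(Constraint(n_id, ca_id, "intra_residue", 5,
                                          rotatable=True))
        if i == n_residues - 1:  # locked C-terminal bond
            constraints.append(Constraint(ca_id, c_id, "linker", 6))
        else:
            constraints.append(Constraint(ca_id, c_id, "intra_residue", 5,
                                          rotatable=True))
        if i > 0:
            constraints.append(Constraint(3 * i - 1, n_id, "linker", 6))
    n_hb = int(rng.poisson(hbonds_per_residue * n_residues))
    placed: set[tuple[int, int]] = set()
    attempts = 0
    while len(placed) < n_hb and attempts < 50 * max(n_hb, 1):
        attempts += 1
        i = int(rng.integers(0, n_residues))
        j = i + 3 + int(rng.geometric(sep_decay)) - 1
        if j >= n_residues:
            continue
        pair = (i, j)
        if pair in placed:
            continue
        placed.add(pair)
    for i, j in sorted(placed):
        constraints.append(Constraint(3 * i + 1, 3 * j + 1, "hbond", 3,
                                      prob=0.5))
    return ConstraintTopology(3 * n_residues, constraints, meta)


# ---------------------------------------------------------------------------
# Synthetic PDB text fixtures (for the structure reader)

_PDB_ATOM = ("ATOM  {serial:>5} {name:<4}{res:>4} {chain}{resseq:>4}    "
             "{x:>8.3f}{y:>8.3f}{z:>8.3f}  1.00  0.00          {elem:>2}\n")


def _pdb_line(serial, name, res, chain, resseq, xyz):
    padded = f" {name:<3}" if len(name) < 4 else name
    return _PDB_ATOM.format(serial=serial, name=padded, res=res, chain=chain,
                            resseq=resseq, x=xyz[0], y=xyz[1], z=xyz[2],
                            elem=name[0])


def write_synthetic_dipeptide_pdb(path) -> None:
    """Write a synthetic two-residue glycine PDB fixture.

    Coordinates are generated, not experimental: backbone bond lengths are
    idealized and the two residues are laid out so that no polar pair comes
    near hydrogen-bonding distance.
    """
    coords = {
        (1, "N"): (0.000, 0.000, 0.000),
        (1, "CA"): (1.460, 0.000, 0.000),
        (1, "C"): (2.010, 1.420, 0.000),
        (1, "O"): (1.280, 2.410, 0.000),
        (2, "N"): (3.340, 1.540, 0.000),
        (2, "CA"): (4.000, 2.840, 0.000),
        (2, "C"): (5.520, 2.700, 0.000),
        (2, "O"): (6.130, 1.630, 0.000),
    }
    with open(path, "w", encoding="utf-8") as fh:
        serial = 1
        for (resseq, name), xyz in coords.items():
            fh.write(_pdb_line(serial, name, "GLY", "A", resseq, xyz))
            serial += 1
        fh.write("END\n")


def write_synthetic_helix_pdb(path, n_residues: int = 10) -> None:
    """Write a synthetic helical glycine chain PDB fixture.

    Alpha carbons sit on a widened helical coil (100 degrees per residue);
    each backbone C is placed exactly 1.33 A from the next residue's N (the
    peptide bond) and each carbonyl O exactly 2.9 A from the backbone N four
    residues ahead, so geometric hydrogen-bond detection finds one i -> i+4
    bond per turn — and nothing else — by construction.  The coil is dilated
    relative to a real helix so that no other donor-acceptor pair falls
    within hydrogen-bonding range; covalent connectivity is template-based,
    so the stretched intra-residue distances are harmless.  Synthetic
    coordinates — not a real structure.
    """
    theta = np.deg2rad(100.0)
    radius, rise = 2.3 * 1.3, 1.5 * 1.3
    ca = np.array([[radius * np.cos(i * theta), radius * np.sin(i * theta),
                    rise * i] for i in range(n_residues + 1)])
    atoms = []  # (resseq, name, xyz)
    n_pos, c_pos = {}, {}
    for i in range(n_residues):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        to_prev = prev_ca - ca[i]
        n_pos[i] = ca[i] + 1.46 * to_prev / np.linalg.norm(to_prev)
    for i in range(n_residues):
        nxt = n_pos[i + 1] if i + 1 < n_residues else ca[i + 1]
        direction = ca[i] - nxt
        c_pos[i] = nxt + 1.33 * direction / np.linalg.norm(direction)
    for i in range(n_residues):
        atoms.append((i + 1, "N", n_pos[i]))
        atoms.append((i + 1, "CA", ca[i]))
        atoms.append((i + 1, "C", c_pos[i]))
        if i + 4 < n_residues:
            direction = c_pos[i] - n_pos[i + 4]
            o = n_pos[i + 4] + 2.9 * direction / np.linalg.norm(direction)
        else:
            o = c_pos[i] + np.array([0.0, 0.0, 1.23])
        atoms.append((i + 1, "O", o))
    with open(path, "w", encoding="utf-8") as fh:
        for serial, (resseq, name, xyz) in enumerate(atoms, start=1):
            fh.write(_pdb_line(serial, name, "GLY", "A", resseq, xyz))
        fh.write("END\n")
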
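"""Constraint-network data model and the constraint topology file (CTF) format.

A molecular constraint network is a multigraph whose vertices are rigid bodies
(each carrying 6 degrees of freedom) and whose edges are typed distance
constraints ("bars").  Covalent constraints are quenched (always present);
hydrogen bonds fluctuate on/off with an occupancy probability ``p``.  Two views
of the network are used downstream:

* the integer view, where each realization keeps or drops every hydrogen bond
  (the classical body-bar pebble game input), and
* the mean-field view, where every vertex pair carries a single weighted edge
  whose capacity is the *average* number of bars — ``bars * prob`` summed over
  parallel constraints (the virtual pebble game input).

The CTF is a line-oriented UTF-8 text format::

    # comment
    vertices <n>
    vertex <id> <label> [calpha]
    edge <u> <v> <kind> <bars> <prob> [rot]

Vertex lines are optional; ids are 0-based contiguous integers.  The trailing
``rot`` token flags a rotatable (torsion) bond.  Occupancy probabilities round
trip at 6 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BARS_BY_KIND",
    "QUENCHED_KINDS",
    "Constraint",
    "VertexMeta",
    "ConstraintTopology",
    "WeightedNetwork",
    "CTFError",
    "read_ctf",
    "write_ctf",
    "aggregate",
    "realize",
]

#: number of distance constraints (bars) consumed by each interaction kind:
#: an intra-residue covalent bond (and a disulfide) consumes five DOF, leaving
#: one for the dihedral angle; the peptide linker consumes six (no rotation);
#: an independent hydrogen bond consumes three.
BARS_BY_KIND = {
    "intra_residue": 5,
    "linker": 6,
    "hbond": 3,
    "disulfide": 5,
}

#: kinds that are always present (probability 1)
QUENCHED_KINDS = frozenset({"intra_residue", "linker", "disulfide"})


class CTFError(ValueError):
    """Raised for malformed or inconsistent CTF content."""


@dataclass(frozen=True)
class Constraint:
    """A typed bar constraint between two rigid bodies.

    ``bars`` is the number of distance constraints the interaction places when
    present; ``prob`` its occupancy probability (1 for quenched kinds).
    ``rotatable`` marks 5-bar covalent bonds that define backbone torsions.
    """

    u: int
    v: int
    kind: str
    bars: int
    prob: float = 1.0
    rotatable: bool = False

    def validate(self) -> None:
        if self.u == self.v:
            raise CTFError(f"self-loop constraint on vertex {self.u}")
        if self.kind not in BARS_BY_KIND:
            raise CTFError(f"unknown constraint kind {self.kind!r}")
        if self.bars != BARS_BY_KIND[self.kind]:
            raise CTFError(
                f"kind {self.kind!r} must carry {BARS_BY_KIND[self.kind]} bars, "
                f"got {self.bars}"
            )
        if not 0.0 <= self.prob <= 1.0:
            raise CTFError(f"probability {self.prob} outside [0, 1]")
        if self.kind in QUENCHED_KINDS and self.prob != 1.0:
            raise CTFError(f"quenched kind {self.kind!r} requires prob=1")


@dataclass
class VertexMeta:
    """Optional per-vertex annotation (atom provenance and alpha-carbon flag)."""

    label: str
    calpha: bool = False
    chain: str | None = None
    residue: int | None = None
    atom: str | None = None


@dataclass
class ConstraintTopology:
    """The CTF in memory: a typed constraint multigraph over rigid bodies.

    Vertex ids are 0-based contiguous integers.  Constraint order is preserved
    — the pebble engines insert edges in list order, so order matters for
    bit-reproducibility (final DOF totals are order-invariant).
    """

    n_vertices: int
    constraints: list[Constraint] = field(default_factory=list)
    vertex_meta: dict[int, VertexMeta] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_vertices < 1:
            raise CTFError("topology needs at least one vertex")
        for c in self.constraints:
            c.validate()
            if not (0 <= c.u < self.n_vertices and 0 <= c.v < self.n_vertices):
                raise CTFError(f"constraint ({c.u},{c.v}) references missing vertex")
        for vid in self.vertex_meta:
            if not 0 <= vid < self.n_vertices:
                raise CTFError(f"vertex meta for missing vertex {vid}")

    def label(self, vid: int) -> str:
        meta = self.vertex_meta.get(vid)
        return meta.label if meta is not None else str(vid)

    @property
    def calpha_ids(self) -> list[int]:
        return [v for v, m in sorted(self.vertex_meta.items()) if m.calpha]

    @property
    def hbond_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.constraints) if c.kind == "hbond"]

    @property
    def rotatable_constraints(self) -> list[Constraint]:
        return [c for c in self.constraints if c.rotatable]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConstraintTopology):
            return NotImplemented
        return (
            self.n_vertices == other.n_vertices
            and self.constraints == other.constraints
            and {v: (m.label, m.calpha) for v, m in self.vertex_meta.items()}
            == {v: (m.label, m.calpha) for v, m in other.vertex_meta.items()}
        )


@dataclass
class WeightedNetwork:
    """Mean-field view: one weighted edge per vertex pair.

    ``edges`` holds ``(u, v, capacity)`` records with ``u < v``, in first-seen
    order of the underlying constraint list; the capacity is the expected
    number of bars between the pair.
    """

    n_vertices: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for u, v, cap in self.edges:
            if u == v:
                raise CTFError("self-loop edge")
            if cap < 0:
                raise CTFError("negative capacity")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise CTFError(f"duplicate weighted edge {key}")
            seen.add(key)


# ---------------------------------------------------------------------------
# CTF reader / writer

def _format_prob(p: float) -> str:
    return f"{p:.6g}"


def read_ctf(path) -> ConstraintTopology:
    """Parse a CTF file into a validated :class:`ConstraintTopology`."""
    n_vertices = None
    constraints: list[Constraint] = []
    vertex_meta: dict[int, VertexMeta] = {}
    labels_to_ids: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            tag = tokens[0]
            try:
                if tag == "vertices":
                    if n_vertices is not None:
                        raise CTFError("duplicate 'vertices' header")
                    n_vertices = int(tokens[1])
                elif tag == "vertex":
                    vid = int(tokens[1])
                    if vid in vertex_meta:
                        raise CTFError(f"duplicate vertex declaration {vid}")
                    label = tokens[2]
                    if label in labels_to_ids:
                        raise CTFError(f"duplicate vertex label {label!r}")
                    calpha = len(tokens) > 3 and tokens[3] == "calpha"
                    meta = VertexMeta(label=label, calpha=calpha)
                    _parse_provenance_label(meta)
                    vertex_meta[vid] = meta
                    labels_to_ids[label] = vid
                elif tag == "edge":
                    u, v = int(tokens[1]), int(tokens[2])
                    kind = tokens[3]
                    bars = int(tokens[4])
                    prob = float(tokens[5])
                    rotatable = len(tokens) > 6 and tokens[6] == "rot"
                    constraints.append(
                        Constraint(u, v, kind, bars, prob, rotatable)
                    )
                else:
                    raise CTFError(f"unknown record {tag!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, CTFError):
                    raise CTFError(f"line {lineno}: {exc}") from None
                raise CTFError(f"line {lineno}: malformed record {line!r}") from exc
    if n_vertices is None:
        raise CTFError("missing 'vertices' header")
    topo = ConstraintTopology(n_vertices, constraints, vertex_meta)
    try:
        topo.validate()
    except CTFError as exc:
        raise CTFError(f"{path}: {exc}") from None
    return topo


def _parse_provenance_label(meta: VertexMeta) -> None:
    # labels written by the protein builder encode "chain:resseq:atom"
    parts = meta.label.split(":")
    if len(parts) == 3:
        try:
            meta.chain, meta.residue, meta.atom = parts[0], int(parts[1]), parts[2]
        except ValueError:
            pass


def write_ctf(topology: ConstraintTopology, path) -> None:
    """Write a topology to ``path``; ``read_ctf`` recovers an equal topology."""
    topology.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"vertices {topology.n_vertices}\n")
        for vid in sorted(topology.vertex_meta):
            meta = topology.vertex_meta[vid]
            flag = " calpha" if meta.calpha else ""
            fh.write(f"vertex {vid} {meta.label}{flag}\n")
        for c in topology.constraints:
            rot = " rot" if c.rotatable else ""
            fh.write(
                f"edge {c.u} {c.v} {c.kind} {c.bars} {_format_prob(c.prob)}{rot}\n"
            )


# ---------------------------------------------------------------------------
# Aggregation (VPG view) and realization (PG view)

def aggregate(topology: ConstraintTopology, p: float | None = None) -> WeightedNetwork:
    """Collapse the multigraph into the single-edge weighted (VPG) view.

    Each unordered pair gets one edge of capacity ``sum(bars * prob)`` over its
    constraints.  When ``p`` is given it overrides the stored occupancy of
    every hydrogen bond (the global dilution parameter); quenched constraints
    always contribute their full bar count.  Pairs whose capacity comes out at
    exactly zero (hydrogen-bond-only pairs at ``p = 0``) are dropped.
    """
    if p is not None and not 0.0 <= p <= 1.0:
        raise ValueError(f"dilution probability {p} outside [0, 1]")
    topology.validate()
    capacity: dict[tuple[int, int], float] = {}
    order: list[tuple[int, int]] = []
    for c in topology.constraints:
        key = (min(c.u, c.v), max(c.u, c.v))
        prob = c.prob
        if c.kind == "hbond" and p is not None:
            prob = p
        if key not in capacity:
            capacity[key] = 0.0
            order.append(key)
        capacity[key] += c.bars * prob
    edges = [(u, v, capacity[(u, v)]) for (u, v) in order if capacity[(u, v)] > 0.0]
    return WeightedNetwork(topology.n_vertices, edges)


def realize(
    topology: ConstraintTopology, p: float, rng: np.random.Generator
) -> ConstraintTopology:
    """Draw one integer (PG) realization of the fluctuating network.

    Every hydrogen bond is kept with its full 3 bars iff an independent uniform
    draw falls below ``p``; quenched constraints are always kept.  Constraint
    order is preserved for the surviving constraints.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"dilution probability {p} outside [0, 1]")
    kept: list[Constraint] = []
    for c in topology.constraints:
        if c.kind == "hbond":
            if rng.uniform() < p:
                kept.append(replace(c, prob=1.0))
        else:
            kept.append(c)
    return ConstraintTopology(topology.n_vertices, kept, dict(topology.vertex_meta))
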
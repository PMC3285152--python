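"""Ensemble-averaged pebble-game reference and the brute-force rank oracle.

The integer pebble game describes one network realization; thermodynamic-style
averages need the whole ensemble of hydrogen-bond on/off patterns.  This
module provides Monte-Carlo sampling over realizations (`mc_ensemble`), exact
enumeration of all ``2^m`` subsets when the hydrogen-bond count ``m`` is small
(`exact_ensemble`), and an independent linear-programming oracle for the
body-bar rank used to validate the engine on tiny networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .engine import DOF_PER_BODY, run
from .network import ConstraintTopology, WeightedNetwork, aggregate, realize

__all__ = [
    "EnsembleResult",
    "mc_ensemble",
    "exact_ensemble",
    "polymatroid_rank_oracle",
    "shared_dof_oracle",
]

#: statistics that the ensemble accumulators know how to collect
COLLECTABLE = ("corigid", "shared_dof", "torsions", "cluster_sizes", "labels")


@dataclass
class EnsembleResult:
    """Accumulated statistics over pebble-game realizations.

    ``weights`` sums to ``n_realizations`` for Monte-Carlo ensembles and to 1
    for exact enumerations; matrix statistics are indexed by ``vertices``.
    ``torsion_votes`` holds (rigid, flexible) vote mass per torsion, in the
    same weight units.
    """

    p: float
    n_realizations: int
    weights: np.ndarray
    vertices: list[int] = field(default_factory=list)
    corigid_freq: np.ndarray | None = None
    mean_shared_dof: np.ndarray | None = None
    torsions: list[tuple[int, int]] = field(default_factory=list)
    torsion_votes: np.ndarray | None = None
    cluster_sizes_per_realization: list[list[int]] | None = None
    labels_per_realization: list[list[int]] | None = None

    @property
    def torsion_rigid_frac(self) -> np.ndarray:
        if self.torsion_votes is None:
            raise ValueError("torsion votes were not collected")
        total = self.torsion_votes.sum(axis=1)
        return self.torsion_votes[:, 0] / total


class _Accumulator:
    def __init__(self, topology: ConstraintTopology, collect, vertices, torsions):
        unknown = set(collect) - set(COLLECTABLE)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")
        if vertices is None:
            vertices = topology.calpha_ids or list(range(topology.n_vertices))
        if torsions is None:
            torsions = [(c.u, c.v) for c in topology.rotatable_constraints]
        self.collect = set(collect)
        self.vertices = list(vertices)
        self.torsions = list(torsions)
        nv = len(self.vertices)
        self.weights: list[float] = []
        self.corigid = np.zeros((nv, nv)) if "corigid" in collect else None
        self.shared = np.zeros((nv, nv)) if "shared_dof" in collect else None
        self.votes = (np.zeros((len(self.torsions), 2))
                      if "torsions" in collect else None)
        self.sizes = [] if "cluster_sizes" in collect else None
        self.labels = [] if "labels" in collect else None

    def add(self, state, weight: float) -> None:
        self.weights.append(weight)
        need_labels = self.collect & {"corigid", "torsions", "cluster_sizes",
                                      "labels"}
        labels = state.rigid_cluster_decomposition().label if need_labels else None
        if self.corigid is not None:
            lab = np.asarray([labels[v] for v in self.vertices])
            self.corigid += weight * (lab[:, None] == lab[None, :])
        if self.shared is not None:
            for i, a in enumerate(self.vertices):
                for j in range(i + 1, len(self.vertices)):
                    s = state.shared_excess_dof(a, self.vertices[j]) / DOF_PER_BODY
                    self.shared[i, j] += weight * s
                    self.shared[j, i] += weight * s
        if self.votes is not None:
            for k, (a, b) in enumerate(self.torsions):
                rigid = labels[a] == labels[b]
                self.votes[k, 0 if rigid else 1] += weight
        if self.sizes is not None:
            counts: dict[int, int] = {}
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            self.sizes.append(sorted(counts.values(), reverse=True))
        if self.labels is not None:
            self.labels.append(list(labels))

    def result(self, p: float, n_realizations: int) -> EnsembleResult:
        total = sum(self.weights)
        return EnsembleResult(
            p=p,
            n_realizations=n_realizations,
            weights=np.asarray(self.weights),
            vertices=self.vertices,
            corigid_freq=None if self.corigid is None else self.corigid / total,
            mean_shared_dof=None if self.shared is None else self.shared / total,
            torsions=self.torsions,
            torsion_votes=self.votes,
            cluster_sizes_per_realization=self.sizes,
            labels_per_realization=self.labels,
        )


def mc_ensemble(
    topology: ConstraintTopology,
    p: float,
    n: int,
    seed: int,
    collect=("corigid", "torsions", "cluster_sizes"),
    vertices=None,
    torsions=None,
) -> EnsembleResult:
    """Monte-Carlo ensemble of ``n`` integer pebble-game realizations.

    Each realization draws an independent hydrogen-bond pattern at occupancy
    ``p`` (child random streams spawned by counter from ``seed``, so results
    are reproducible regardless of execution order) and runs the integer game.
    """
    if n < 1:
        raise ValueError("need at least one realization")
    acc = _Accumulator(topology, collect, vertices, torsions)
    for r in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        net = aggregate(realize(topology, p, rng))
        state = run(net, mode="integer")
        acc.add(state, 1.0)
    return acc.result(p, n)


def exact_ensemble(
    topology: ConstraintTopology,
    p: float,
    collect=("corigid", "torsions", "cluster_sizes"),
    vertices=None,
    torsions=None,
    max_hbonds: int = 20,
) -> EnsembleResult:
    """Exhaustive weighted average over all hydrogen-bond subsets.

    Each of the ``2^m`` on/off patterns is run through the integer game and
    weighted ``p^k (1-p)^(m-k)``; this is the exact quantity the Monte-Carlo
    ensemble estimates, and is feasible only for small ``m``.
    """
    hb = topology.hbond_indices
    m = len(hb)
    if m > max_hbonds:
        raise ValueError(
            f"{m} hydrogen bonds would need 2^{m} evaluations; "
            "use mc_ensemble for large networks"
        )
    acc = _Accumulator(topology, collect, vertices, torsions)
    hb_set = set(hb)
    for pattern in itertools.product((False, True), repeat=m):
        k = sum(pattern)
        weight = (p ** k) * ((1.0 - p) ** (m - k))
        if weight == 0.0:
            continue
        on = {hb[i] for i, keep in enumerate(pattern) if keep}
        constraints = []
        for i, c in enumerate(topology.constraints):
            if i in hb_set:
                if i in on:  # a surviving hydrogen bond is fully present
                    constraints.append(replace(c, prob=1.0))
            else:
                constraints.append(c)
        sub = ConstraintTopology(topology.n_vertices, constraints,
                                 dict(topology.vertex_meta))
        state = run(aggregate(sub), mode="integer")
        acc.add(state, weight)
    return acc.result(p, n_realizations=2 ** m)


# ---------------------------------------------------------------------------
# Independent rank oracle (linear programming over subset counts)

def polymatroid_rank_oracle(network: WeightedNetwork, max_vertices: int = 7
                            ) -> float:
    """Body-bar rank of a weighted network by brute-force linear programming.

    Maximizes ``sum(x_e)`` subject to ``0 <= x_e <= c_e`` and, for every
    vertex subset ``S`` with at least two members, ``sum_{e in S} x_e <=
    6|S| - 6``.  The engine's free DOF must equal ``6|V|`` minus this rank.
    Deliberately independent of the pebble engine; exponential in ``|V|``.
    """
    n = network.n_vertices
    if n > max_vertices:
        raise ValueError(f"oracle limited to {max_vertices} vertices, got {n}")
    edges = network.edges
    if not edges:
        return 0.0
    n_e = len(edges)
    rows, rhs = [], []
    for size in range(2, n + 1):
        for subset in itertools.combinations(range(n), size):
            s = set(subset)
            row = [1.0 if (u in s and v in s) else 0.0 for u, v, _ in edges]
            if any(row):
                rows.append(row)
                rhs.append(DOF_PER_BODY * size - DOF_PER_BODY)
    bounds = [(0.0, cap) for _, _, cap in edges]
    res = linprog(
        c=[-1.0] * n_e,
        A_ub=np.asarray(rows) if rows else None,
        b_ub=np.asarray(rhs) if rows else None,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"rank LP failed: {res.message}")
    return -res.fun


def shared_dof_oracle(network: WeightedNetwork, ref: int, query: int) -> float:
    """Oracle for the shared excess DOF of a vertex pair.

    Equals the rank increase caused by a hypothetical capacity-6 edge between
    the pair — exactly the hypothetical-edge cover test used by the rigid
    cluster decomposition, evaluated by linear programming instead of pebbles.
    """
    if ref == query:
        return 0.0
    base = polymatroid_rank_oracle(network)
    extended = WeightedNetwork(
        network.n_vertices,
        list(network.edges) + [(ref, query, float(DOF_PER_BODY))],
    )
    # the pair may already carry an edge; rank handles parallels additively
    extended.edges = _merge_parallel(extended.edges)
    return polymatroid_rank_oracle(extended) - base


def _merge_parallel(edges):
    capacity: dict[tuple[int, int], float] = {}
    order = []
    for u, v, cap in edges:
        key = (min(u, v), max(u, v))
        if key not in capacity:
            capacity[key] = 0.0
            order.append(key)
        capacity[key] += cap
    return [(u, v, capacity[(u, v)]) for u, v in order]
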
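"""The body-bar pebble engine, in integer (PG) and fractional (VPG) modes.

One flow engine serves both games.  Every rigid body starts with 6 free
pebbles (its rigid-body degrees of freedom).  Inserting an edge of capacity
``c`` first gathers and holds 6 pebbles on one endpoint, then gathers up to
``c`` on the other and lays them on the edge; pebbles are gathered through
breadth-first searches that reclaim a vertex's own pebbles from edges by
letting the neighbor on the far side cover them instead.  A search that fails
to find enough pebbles identifies a minimally rigid region, which is condensed
into a single supervertex retaining its 6 trivial DOF.

Pebble ownership is conserved: each live supervertex owns exactly 6 pebbles,
split between its free pool and the edge sides it covers.  The global ledger
``6 N = free_total + consumed`` (covers plus condensation charges) holds after
every operation and is checked by the test suite.

The only difference between the two modes is the number domain: the PG plays
with integer bar counts on a realized network; the VPG plays the identical
moves with real-valued capacities (mean bar counts), where a fractional pebble
is read as the probability of finding a degree of freedom there.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .network import WeightedNetwork

__all__ = [
    "PebbleEngineError",
    "PebbleState",
    "RigidClusterLabels",
    "init_state",
    "run",
]

DOF_PER_BODY = 6


class PebbleEngineError(RuntimeError):
    """An engine-internal inconsistency (should never occur on valid input)."""


class _Edge:
    """Aggregated live edge between two supervertices.

    ``cover`` maps each incident supervertex root to the amount of its own
    pebbles currently lying on the edge; ``cap`` is the total capacity.
    """

    __slots__ = ("cap", "cover")

    def __init__(self, a: int, b: int, cap: float):
        self.cap = cap
        self.cover: dict[int, float] = {a: 0.0, b: 0.0}

    def total_cover(self) -> float:
        return sum(self.cover.values())


@dataclass
class RigidClusterLabels:
    """Partition of the original vertices into rigid clusters."""

    label: list[int]

    @property
    def cluster_sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for lab in self.label:
            counts[lab] = counts.get(lab, 0) + 1
        return sorted(counts.values(), reverse=True)

    @property
    def n_clusters(self) -> int:
        return len(set(self.label))


class PebbleState:
    """Mutable engine state: free pebbles, directed covers, condensation map."""

    def __init__(self, network: WeightedNetwork, mode: str = "fractional",
                 tol: float = 1e-9):
        if mode not in ("integer", "fractional"):
            raise ValueError(f"unknown mode {mode!r}")
        if tol <= 0:
            raise ValueError("tol must be positive")
        network.validate()
        if mode == "integer":
            for u, v, cap in network.edges:
                if cap != int(cap):
                    raise ValueError(
                        f"integer mode requires integer capacities, got {cap} "
                        f"on edge ({u},{v})"
                    )
        self.mode = mode
        self.tol = tol
        self.n_original = network.n_vertices
        self._parent = list(range(network.n_vertices))
        self.free: dict[int, float] = {v: float(DOF_PER_BODY)
                                       for v in range(network.n_vertices)}
        self.adj: dict[int, dict[int, _Edge]] = {
            v: {} for v in range(network.n_vertices)
        }
        self.consumed = 0.0
        self.absorbed_redundant = 0.0
        self._support_parent = list(range(network.n_vertices))
        self._pending = list(network.edges)
        self._run_complete = False

    # -- union-find ---------------------------------------------------------

    def find(self, v: int) -> int:
        root = v
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[v] != root:
            self._parent[v], v = root, self._parent[v]
        return root

    def _support_find(self, v: int) -> int:
        root = v
        while self._support_parent[root] != root:
            root = self._support_parent[root]
        while self._support_parent[v] != root:
            self._support_parent[v], v = root, self._support_parent[v]
        return root

    # -- ledger -------------------------------------------------------------

    def free_dof(self) -> float:
        """Total free pebbles over live supervertices."""
        return sum(self.free.values())

    def ledger_residual(self) -> float:
        """``6N − free_total − consumed``; zero (to tolerance) when healthy."""
        return DOF_PER_BODY * self.n_original - self.free_dof() - self.consumed

    def n_components(self) -> int:
        """Connected components of the inserted-edge support (isolated
        vertices count as their own component)."""
        return len({self._support_find(v) for v in range(self.n_original)})

    def excess_dof(self) -> float:
        """Free DOF beyond the 6 trivial rigid-body DOF of each component."""
        return self.free_dof() - DOF_PER_BODY * self.n_components()

    # -- pebble search ------------------------------------------------------

    def collect_pebbles(self, target: int, amount: float,
                        pinned: int | None = None) -> tuple[float, set[int]]:
        """Gather up to ``amount`` free pebbles on ``target``.

        Repeated BFS passes pull pebbles along augmenting paths; a pass that
        finds no source (or makes progress below tolerance) ends the search.
        Returns the pebbles now free on the target and the set of supervertex
        roots visited in the final pass.  A pinned vertex keeps its 6 pebbles
        immobile and is flagged visited up front, so the search neither takes
        its pebbles nor expands through it.
        """
        tol = self.tol
        t = self.find(target)
        pin = self.find(pinned) if pinned is not None else None
        if pin == t:
            raise PebbleEngineError("cannot pin the search target")
        if self.free[t] >= amount - tol:
            return self.free[t], {t}
        max_passes = 1000 + 50 * self.n_original
        for _ in range(max_passes):
            visited: set[int] = {t}
            if pin is not None:
                visited.add(pin)
            parent_ptr: dict[int, int] = {}
            queue: deque[int] = deque([t])
            source: int | None = None
            while queue and source is None:
                x = queue.popleft()
                edges_x = self.adj[x]
                for y in sorted(edges_x):
                    if y in visited:
                        continue
                    if edges_x[y].cover[x] <= tol:
                        continue
                    visited.add(y)
                    parent_ptr[y] = x
                    if self.free[y] > tol:
                        source = y
                        break
                    queue.append(y)
            if source is None:
                return self.free[t], visited
            # bottleneck along the tree path source -> t
            path: list[int] = [source]
            while path[-1] != t:
                path.append(parent_ptr[path[-1]])
            path.reverse()  # t ... source
            q = min(self.free[source], amount - self.free[t])
            for a, b in zip(path, path[1:]):
                q = min(q, self.adj[a][b].cover[a])
            if q <= tol:
                # float dust: no meaningful progress, treat as failed search
                return self.free[t], visited
            for a, b in zip(path, path[1:]):
                edge = self.adj[a][b]
                edge.cover[a] -= q
                edge.cover[b] += q
            self.free[source] -= q
            self.free[t] += q
            if self.free[t] >= amount - tol:
                return self.free[t], visited
        raise PebbleEngineError("pebble search failed to terminate")

    # -- edge insertion and condensation ------------------------------------

    def insert_edge(self, u: int, v: int, capacity: float) -> None:
        """Insert one weighted edge, covering it or condensing on failure."""
        tol = self.tol
        if capacity < 0:
            raise ValueError("negative capacity")
        if u == v:
            raise ValueError("self-loop edge")
        if capacity <= tol:
            return  # registration only: a zero-capacity edge absorbs nothing
        su, sv = self._support_find(u), self._support_find(v)
        if su != sv:
            self._support_parent[max(su, sv)] = min(su, sv)
        ru, rv = self.find(u), self.find(v)
        if ru == rv:
            # internal to an existing rigid supervertex: wholly redundant
            self.absorbed_redundant += capacity
            return
        edge = self.adj[ru].get(rv)
        if edge is None:
            edge = _Edge(ru, rv, capacity)
            self.adj[ru][rv] = edge
            self.adj[rv][ru] = edge
        else:
            edge.cap += capacity
        gathered, _ = self.collect_pebbles(ru, DOF_PER_BODY)
        if gathered < DOF_PER_BODY - tol:
            raise PebbleEngineError(
                "could not gather 6 pebbles on an endpoint; state is corrupt"
            )
        gathered, visited = self.collect_pebbles(rv, capacity, pinned=ru)
        covered = min(capacity, gathered)
        if covered > 0:
            self.free[rv] -= covered
            edge.cover[rv] += covered
            self.consumed += covered
        if covered < capacity - tol:
            self.absorbed_redundant += capacity - covered
            self.condense(visited | {ru, rv})

    def condense(self, vertices) -> None:
        """Collapse a failed-search region into one supervertex with 6 DOF."""
        roots = {self.find(x) for x in vertices}
        if len(roots) <= 1:
            return
        r_new = min(roots)
        freed = sum(self.free[r] for r in roots)
        merged: dict[int, _Edge] = {}
        for r in roots:
            for nbr, edge in self.adj[r].items():
                if nbr in roots:
                    # internal edge retired; its covers stay charged
                    continue
                # external edge: re-attach to r_new, summing parallels
                tgt = merged.get(nbr)
                if tgt is None:
                    new_edge = _Edge(r_new, nbr, edge.cap)
                    new_edge.cover[r_new] = edge.cover[r]
                    new_edge.cover[nbr] = edge.cover[nbr]
                    merged[nbr] = new_edge
                else:
                    tgt.cap += edge.cap
                    tgt.cover[r_new] += edge.cover[r]
                    tgt.cover[nbr] += edge.cover[nbr]
                del self.adj[nbr][r]
        for r in roots:
            del self.free[r]
            del self.adj[r]
            self._parent[r] = r_new
        self._parent[r_new] = r_new
        self.free[r_new] = float(DOF_PER_BODY)
        self.adj[r_new] = merged
        for nbr, edge in merged.items():
            self.adj[nbr][r_new] = edge
        # 6(k-1) DOF die with the merge; swallowed free pebbles and internal
        # covers are charged to the ledger (covers were already consumed).
        self.consumed += freed - DOF_PER_BODY

    def run(self) -> "PebbleState":
        """Insert all pending edges in list order."""
        for u, v, cap in self._pending:
            self.insert_edge(u, v, cap)
        self._pending = []
        self._run_complete = True
        return self

    # -- state snapshot (probes must not observably mutate the state) -------

    def _snapshot(self):
        covers = []
        seen: set[int] = set()
        for r, nbrs in self.adj.items():
            for nbr, edge in nbrs.items():
                if nbr in seen:
                    continue
                covers.append((edge, dict(edge.cover)))
            seen.add(r)
        return dict(self.free), covers

    def _restore(self, snap) -> None:
        free, covers = snap
        self.free = dict(free)
        for edge, cover in covers:
            edge.cover = dict(cover)

    # -- rigidity queries ----------------------------------------------------

    def _require_run(self) -> None:
        if not self._run_complete:
            raise PebbleEngineError("query requires a completed run")

    def rigid_cluster_decomposition(self) -> RigidClusterLabels:
        """Partition vertices into rigid clusters.

        For an unlabeled vertex, 6 pebbles are gathered and pinned on it, and
        each candidate partner is probed: if any excess pebbles can be
        gathered on the partner the pair is flexible; a failed search labels
        every visited supervertex into the cluster at once.  The converged
        covers are restored afterwards.
        """
        self._require_run()
        tol = self.tol
        labels = [-1] * self.n_original
        snap = self._snapshot()
        next_label = 0
        originals_by_root: dict[int, list[int]] = {}
        for v in range(self.n_original):
            originals_by_root.setdefault(self.find(v), []).append(v)
        for v in range(self.n_original):
            if labels[v] != -1:
                continue
            rv = self.find(v)
            gathered, _ = self.collect_pebbles(rv, DOF_PER_BODY)
            if gathered < DOF_PER_BODY - tol:
                raise PebbleEngineError("could not gather 6 pebbles for RCD pin")
            cluster_roots = {rv}
            for w in sorted(originals_by_root):
                if w == rv or w in cluster_roots:
                    continue
                if labels[originals_by_root[w][0]] != -1:
                    continue
                gathered, visited = self.collect_pebbles(
                    w, DOF_PER_BODY, pinned=rv
                )
                if gathered > tol:
                    continue  # excess DOF found: different cluster
                cluster_roots |= visited
            for r in cluster_roots:
                for orig in originals_by_root.get(r, ()):
                    labels[orig] = next_label
            next_label += 1
            self._restore(snap)
        return RigidClusterLabels(labels)

    def shared_excess_dof(self, ref: int, query: int) -> float:
        """Maximum excess DOF shared by two bodies, in ``[0, 6]``.

        The 6 trivial DOF are pinned on the reference body, then a pebble
        search gathers the maximum number of internal DOF on the query body.
        Symmetric in its arguments; 0 for co-rigid pairs (and for a vertex
        with itself), 6 for fully independent bodies.
        """
        self._require_run()
        if ref == query:
            return 0.0
        r_ref, r_query = self.find(ref), self.find(query)
        if r_ref == r_query:
            return 0.0
        snap = self._snapshot()
        try:
            gathered, _ = self.collect_pebbles(r_ref, DOF_PER_BODY)
            if gathered < DOF_PER_BODY - self.tol:
                raise PebbleEngineError("could not gather 6 pebbles on reference")
            gathered, _ = self.collect_pebbles(
                r_query, DOF_PER_BODY, pinned=r_ref
            )
        finally:
            self._restore(snap)
        return min(gathered, float(DOF_PER_BODY))


def init_state(network: WeightedNetwork, mode: str = "fractional",
               tol: float = 1e-9) -> PebbleState:
    """Create an engine state with 6 free pebbles per body and no covers."""
    return PebbleState(network, mode=mode, tol=tol)


def run(network: WeightedNetwork, mode: str = "fractional",
        tol: float = 1e-9) -> PebbleState:
    """Play the pebble game over all edges of ``network`` in list order."""
    return init_state(network, mode=mode, tol=tol).run()
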
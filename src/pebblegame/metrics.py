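"""Similarity and characterization metrics for rigidity descriptions.

Comparison metrics between the mean-field (VPG) description and the
ensemble-averaged integer pebble game: the Rand Measure over rigid cluster
partitions, the per-torsion Agreement Measure, binary rigid cluster maps
(RCM) and continuous mechanical coupling maps (MCM), the rigid cluster
susceptibility (RCS) and average cluster size (ACS), the hydrogen-bond
dilution sweep, and the locators for the worst-agreement point ``p_dagger``
(minimum Rand Measure) and the rigidity transition ``p_t`` (RCS peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import rand_score

from .engine import DOF_PER_BODY, PebbleState, run
from .ensemble import EnsembleResult
from .network import ConstraintTopology, aggregate, realize

__all__ = [
    "DilutionCurve",
    "rand_measure",
    "agreement_measure",
    "torsion_rigidity",
    "rigid_cluster_map",
    "mechanical_coupling_map",
    "composite_map",
    "rigid_cluster_susceptibility",
    "average_cluster_size",
    "dilution_sweep",
    "find_p_worst",
    "find_p_transition",
    "mcm_pearson",
]


def rand_measure(labels_a, labels_b) -> float:
    """Fraction of vertex pairs whose same/different-cluster status agrees.

    1 for identical partitions; 0 only when one partition is a single cluster
    and the other is all singletons.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same vertex set")
    if labels_a.size < 2:
        raise ValueError("Rand Measure needs at least two vertices")
    return float(rand_score(labels_a, labels_b))


def agreement_measure(vpg_rigid: bool, n_disagree: float, n_agree: float,
                      n_total: float) -> float:
    """Signed per-torsion disagreement between the mean-field call and the
    ensemble vote, in ``[-1, 1]``.

    0 whenever the mean-field call matches the ensemble majority; +1 when the
    mean-field game calls the torsion rigid but every realization calls it
    flexible; -1 in the mirrored case.  Small magnitudes flag near-tied votes
    where the mean-field game sits on the minority side.
    """
    if n_total < 1:
        raise ValueError("need at least one realization")
    if abs((n_disagree + n_agree) - n_total) > 1e-9 * max(n_total, 1.0):
        raise ValueError("disagree + agree must equal total")
    sigma = 1.0 if vpg_rigid else -1.0
    return sigma * max(0.0, n_disagree - n_agree) / n_total


def torsion_rigidity(topology: ConstraintTopology, labels,
                     torsions=None) -> list[bool]:
    """Rigid/flexible call per torsion: rigid iff its two endpoint bodies
    share a rigid-cluster label."""
    if torsions is None:
        torsions = [(c.u, c.v) for c in topology.rotatable_constraints]
    out = []
    for u, v in torsions:
        if not (0 <= u < len(labels) and 0 <= v < len(labels)):
            raise ValueError(f"torsion ({u},{v}) references missing vertices")
        out.append(labels[u] == labels[v])
    return out


def rigid_cluster_map(source, calpha_ids=None, majority: float = 0.5
                      ) -> np.ndarray:
    """Binary symmetric co-rigidity matrix over the selected bodies.

    ``source`` is either a per-vertex label array (single run) or a co-rigid
    frequency matrix (ensemble), which is thresholded at ``majority`` — a
    frequency exactly at the threshold counts rigid.  The diagonal is 1 by
    definition.
    """
    source = np.asarray(source)
    if source.ndim == 1:
        if calpha_ids is None:
            calpha_ids = list(range(source.size))
        lab = source[np.asarray(calpha_ids)]
        mat = (lab[:, None] == lab[None, :]).astype(int)
    elif source.ndim == 2:
        mat = (source >= majority).astype(int)
    else:
        raise ValueError("source must be a label vector or frequency matrix")
    np.fill_diagonal(mat, 1)
    return mat


def mechanical_coupling_map(source, calpha_ids=None) -> np.ndarray:
    """Symmetric matrix of shared excess DOF per pair, normalized by 6.

    From a converged :class:`PebbleState` the entries are probed directly;
    from an :class:`EnsembleResult` the realization mean is used.  0 marks a
    co-rigid pair, 1 fully independent bodies; the diagonal is 0.
    """
    if isinstance(source, EnsembleResult):
        if source.mean_shared_dof is None:
            raise ValueError("ensemble did not collect shared-DOF statistics")
        mat = np.array(source.mean_shared_dof, dtype=float)
    elif isinstance(source, PebbleState):
        if calpha_ids is None:
            calpha_ids = list(range(source.n_original))
        n = len(calpha_ids)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = source.shared_excess_dof(calpha_ids[i], calpha_ids[j])
                mat[i, j] = mat[j, i] = s / DOF_PER_BODY
    else:
        raise TypeError("source must be a PebbleState or EnsembleResult")
    np.fill_diagonal(mat, 0.0)
    return mat


def composite_map(vpg_map: np.ndarray, ensemble_map: np.ndarray) -> np.ndarray:
    """Mean-field results in the lower triangle, ensemble in the upper."""
    vpg_map = np.asarray(vpg_map)
    ensemble_map = np.asarray(ensemble_map)
    if vpg_map.shape != ensemble_map.shape:
        raise ValueError("maps must have the same shape")
    out = np.tril(vpg_map, -1) + np.triu(ensemble_map, 1)
    np.fill_diagonal(out, np.diag(vpg_map))
    return out


def rigid_cluster_susceptibility(cluster_sizes) -> float:
    """Reduced second moment of the rigid cluster sizes.

    ``sum(s^2 n_s) / sum(s n_s)`` with the single largest cluster excluded
    (the standard percolation susceptibility convention); a fully rigid
    network (one cluster) gives 0.
    """
    sizes = sorted(cluster_sizes)
    if not sizes:
        raise ValueError("empty cluster size multiset")
    rest = sizes[:-1]  # drop one largest cluster
    if not rest:
        return 0.0
    rest = np.asarray(rest, dtype=float)
    return float((rest ** 2).sum() / rest.sum())


def average_cluster_size(cluster_sizes) -> float:
    """Unweighted arithmetic mean of the rigid cluster sizes."""
    sizes = np.asarray(list(cluster_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("empty cluster size multiset")
    return float(sizes.mean())


@dataclass
class DilutionCurve:
    """Per-``p`` records from a hydrogen-bond dilution sweep."""

    p_grid: np.ndarray
    rm_mean: np.ndarray
    rcs_pg: np.ndarray
    rcs_vpg: np.ndarray
    acs_pg: np.ndarray
    acs_vpg: np.ndarray

    def __post_init__(self):
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        if np.any(np.diff(self.p_grid) <= 0):
            raise ValueError("p grid must be strictly ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "p": self.p_grid,
            "rm_mean": self.rm_mean,
            "rcs_pg": self.rcs_pg,
            "rcs_vpg": self.rcs_vpg,
            "acs_pg": self.acs_pg,
            "acs_vpg": self.acs_vpg,
        })


def dilution_sweep(topology: ConstraintTopology, p_grid, n_realizations: int,
                   seed: int, tol: float = 1e-9) -> DilutionCurve:
    """Sweep the hydrogen-bond occupancy and compare mean-field vs ensemble.

    At each ``p`` the fractional game runs once on the aggregated network and
    ``n_realizations`` integer games run on sampled realizations.  The Rand
    Measure of each realization's rigid cluster decomposition against the
    single mean-field decomposition is averaged; cluster-size statistics
    (RCS, ACS) are recorded for both variants.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(p_grid < 0) or np.any(p_grid > 1):
        raise ValueError("p grid must lie in [0, 1]")
    rm_mean, rcs_pg, rcs_vpg, acs_pg, acs_vpg = ([] for _ in range(5))
    for pi, p in enumerate(p_grid):
        vpg_state = run(aggregate(topology, p), mode="fractional", tol=tol)
        vpg_labels = vpg_state.rigid_cluster_decomposition()
        rcs_vpg.append(rigid_cluster_susceptibility(vpg_labels.cluster_sizes))
        acs_vpg.append(average_cluster_size(vpg_labels.cluster_sizes))
        rms, rcss, acss = [], [], []
        for r in range(n_realizations):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(pi, r)))
            state = run(aggregate(realize(topology, p, rng)), mode="integer")
            labels = state.rigid_cluster_decomposition()
            rms.append(rand_measure(labels.label, vpg_labels.label))
            rcss.append(rigid_cluster_susceptibility(labels.cluster_sizes))
            acss.append(average_cluster_size(labels.cluster_sizes))
        rm_mean.append(float(np.mean(rms)))
        rcs_pg.append(float(np.mean(rcss)))
        acs_pg.append(float(np.mean(acss)))
    return DilutionCurve(p_grid, np.asarray(rm_mean), np.asarray(rcs_pg),
                         np.asarray(rcs_vpg), np.asarray(acs_pg),
                         np.asarray(acs_vpg))


def find_p_worst(curve: DilutionCurve) -> float:
    """The occupancy with the worst (minimum) mean Rand Measure; ties break
    toward smaller ``p``."""
    return float(curve.p_grid[int(np.argmin(curve.rm_mean))])


def find_p_transition(curve: DilutionCurve, which: str = "pg") -> float | None:
    """The rigidity transition: occupancy at the RCS peak.

    Returns ``None`` (no transition) when the susceptibility has no interior
    peak — e.g. a monotone curve for a network that never crosses the
    transition.  Ties break toward smaller ``p``.
    """
    if which not in ("pg", "vpg"):
        raise ValueError("which must be 'pg' or 'vpg'")
    rcs = curve.rcs_pg if which == "pg" else curve.rcs_vpg
    idx = int(np.argmax(rcs))
    if idx == 0 or idx == len(rcs) - 1:
        return None
    return float(curve.p_grid[idx])


def mcm_pearson(mcm_a: np.ndarray, mcm_b: np.ndarray) -> float:
    """Pearson correlation of two coupling maps over their strict upper
    triangles; raises on zero-variance input."""
    mcm_a = np.asarray(mcm_a, dtype=float)
    mcm_b = np.asarray(mcm_b, dtype=float)
    if mcm_a.shape != mcm_b.shape or mcm_a.ndim != 2:
        raise ValueError("maps must be matrices of identical shape")
    iu = np.triu_indices(mcm_a.shape[0], k=1)
    a, b = mcm_a[iu], mcm_b[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    return float(pearsonr(a, b)[0])
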
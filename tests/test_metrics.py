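"""Similarity metrics, cluster statistics, and dilution-curve locators."""

import numpy as np
import pytest

from pebblegame.engine import run
from pebblegame.ensemble import exact_ensemble
from pebblegame.metrics import (
    DilutionCurve,
    agreement_measure,
    average_cluster_size,
    composite_map,
    find_p_transition,
    find_p_worst,
    mcm_pearson,
    mechanical_coupling_map,
    rand_measure,
    rigid_cluster_map,
    rigid_cluster_susceptibility,
    torsion_rigidity,
)
from pebblegame.network import aggregate


class TestRandMeasure:
    def test_identical_partitions_score_one(self):
        assert rand_measure([0, 0, 1, 2], [5, 5, 7, 9]) == 1.0

    def test_one_cluster_vs_singletons_scores_zero(self):
        assert rand_measure([0] * 5, range(5)) == 0.0

    def test_hand_enumerated_three_vertex_case(self):
        # pairs: (0,1) same/diff, (0,2) diff/diff match, (1,2) diff/same
        assert rand_measure([1, 1, 2], [1, 2, 2]) == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = [0, 0, 1, 1, 2], [0, 1, 1, 2, 2]
        assert rand_measure(a, b) == rand_measure(b, a)

    def test_needs_two_vertices(self):
        with pytest.raises(ValueError):
            rand_measure([0], [0])


class TestAgreementMeasure:
    def test_total_disagreement_rigid_prediction(self):
        assert agreement_measure(True, 1000, 0, 1000) == 1.0

    def test_majority_agreement_scores_zero(self):
        assert agreement_measure(True, 400, 600, 1000) == 0.0
        assert agreement_measure(False, 0, 10, 10) == 0.0

    def test_near_tied_vote_small_magnitude(self):
        # flexible call against a 501/499 rigid-majority vote
        assert agreement_measure(False, 501, 499, 1000) == \
            pytest.approx(-0.002)

    def test_bounds(self):
        for vpg_rigid in (True, False):
            for d in range(0, 11):
                am = agreement_measure(vpg_rigid, d, 10 - d, 10)
                assert -1.0 <= am <= 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            agreement_measure(True, 3, 3, 10)


class TestTorsionRigidity:
    def test_same_cluster_is_rigid(self, toy_topology):
        labels = [0] * 8
        assert all(torsion_rigidity(toy_topology, labels))

    def test_bridging_torsion_is_flexible(self, toy_topology):
        labels = list(range(8))
        assert not any(torsion_rigidity(toy_topology, labels))

    def test_missing_vertex_rejected(self, toy_topology):
        with pytest.raises(ValueError):
            torsion_rigidity(toy_topology, [0, 0], torsions=[(0, 5)])


class TestMaps:
    def test_rcm_from_labels_all_one_cluster(self):
        mat = rigid_cluster_map(np.zeros(4, dtype=int))
        assert np.array_equal(mat, np.ones((4, 4), dtype=int))

    def test_rcm_majority_tie_counts_rigid(self):
        freq = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.array_equal(rigid_cluster_map(freq),
                              np.ones((2, 2), dtype=int))
        below = np.array([[1.0, 0.49], [0.49, 1.0]])
        assert rigid_cluster_map(below)[0, 1] == 0

    def test_mcm_extremes(self, triangle):
        state = run(triangle)
        mcm = mechanical_coupling_map(state)
        assert np.all(np.diag(mcm) == 0)
        assert np.array_equal(mcm, mcm.T)
        assert np.all((0 <= mcm) & (mcm <= 1))

    def test_mcm_from_ensemble_mean(self, toy_topology):
        result = exact_ensemble(toy_topology, 0.5, collect=("shared_dof",),
                                vertices=list(range(8)))
        mcm = mechanical_coupling_map(result)
        assert mcm.shape == (8, 8)
        assert np.array_equal(mcm, mcm.T)

    def test_composite_layout(self):
        lower = np.full((3, 3), 2.0)
        upper = np.full((3, 3), 7.0)
        out = composite_map(lower, upper)
        assert out[2, 0] == 2.0 and out[0, 2] == 7.0
        assert out[1, 1] == 2.0


class TestClusterStatistics:
    @pytest.mark.parametrize("sizes,expected", [
        ([10], 0.0),                  # fully rigid: nothing but the largest
        ([1] * 6, 1.0),               # all singletons
        ([5, 3, 1], 2.5),             # (9 + 1) / (3 + 1)
    ])
    def test_susceptibility_hand_values(self, sizes, expected):
        assert rigid_cluster_susceptibility(sizes) == pytest.approx(expected)

    @pytest.mark.parametrize("sizes,expected", [
        ([5, 3, 1], 3.0),
        ([7], 7.0),
        ([1, 1, 1], 1.0),
    ])
    def test_average_cluster_size(self, sizes, expected):
        assert average_cluster_size(sizes) == pytest.approx(expected)

    def test_empty_multisets_rejected(self):
        with pytest.raises(ValueError):
            rigid_cluster_susceptibility([])
        with pytest.raises(ValueError):
            average_cluster_size([])


def make_curve(rm, rcs):
    n = len(rm)
    grid = np.linspace(0, 1, n)
    z = np.zeros(n)
    return DilutionCurve(grid, np.asarray(rm, dtype=float),
                         np.asarray(rcs, dtype=float),
                         np.asarray(rcs, dtype=float), z, z)


class TestCurveLocators:
    def test_unimodal_peak_located(self):
        curve = make_curve(rm=[1, 0.8, 0.5, 0.8, 1],
                           rcs=[0.1, 0.5, 2.0, 0.5, 0.1])
        assert find_p_worst(curve) == 0.5
        assert find_p_transition(curve, "pg") == 0.5

    def test_monotone_rcs_flags_no_transition(self):
        curve = make_curve(rm=[1, 0.9, 0.8, 0.7, 0.6],
                           rcs=[0.1, 0.2, 0.3, 0.4, 0.5])
        assert find_p_transition(curve, "pg") is None

    def test_rm_tie_breaks_toward_smaller_p(self):
        curve = make_curve(rm=[1, 0.5, 0.5, 1, 1], rcs=[0, 1, 1, 1, 0])
        assert find_p_worst(curve) == 0.25
        assert find_p_transition(curve, "pg") == 0.25

    def test_grid_must_ascend(self):
        with pytest.raises(ValueError):
            DilutionCurve(np.array([0.0, 0.0, 1.0]), np.zeros(3),
                          np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))


class TestMcmPearson:
    def test_identical_maps_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(5, 5))
        m = (m + m.T) / 2
        assert mcm_pearson(m, m) == pytest.approx(1.0)

    def test_constant_map_rejected(self):
        m = np.zeros((4, 4))
        other = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ValueError, match="constant"):
            mcm_pearson(m, other)

    def test_hand_three_by_three_case(self):
        a = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        b = np.array([[0, 2.0, 1.0], [2.0, 0, 5.0], [1.0, 5.0, 0]])
        # upper triangles (1,2,3) vs (2,1,5): r = 0.3273268...
        expected = np.corrcoef([1, 2, 3], [2, 1, 5])[0, 1]
        assert mcm_pearson(a, b) == pytest.approx(expected)


class TestVpgEquivalenceAtSuppressedFluctuations:
    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_mcm_identical_when_fluctuations_vanish(self, toy_topology, p):
        vertices = list(range(8))
        exact = exact_ensemble(toy_topology, p, collect=("shared_dof",),
                               vertices=vertices)
        vpg = run(aggregate(toy_topology, p))
        mcm_vpg = mechanical_coupling_map(vpg, vertices)
        mcm_pg = mechanical_coupling_map(exact)
        assert np.allclose(mcm_vpg, mcm_pg, atol=0)
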
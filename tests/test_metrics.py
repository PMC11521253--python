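"""Landings-weighted functional diversity metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitdiv import (AssemblageWeights, PooledSpace, compute_fd,
                      functional_dispersion, functional_divergence,
                      functional_evenness, functional_richness, standardize_fric)
from traitdiv.metrics import minimum_spanning_tree_edges

from oracles import brute_fdis, brute_fdiv, brute_feve, shoelace_area


class TestFunctionalRichness:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        volume, flag = functional_richness(pts, 2)
        assert volume == pytest.approx(1.0) and flag is None

    def test_collinear_is_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        volume, flag = functional_richness(pts, 2)
        assert volume == 0.0 and flag == "degenerate"

    def test_matches_shoelace_oracle(self, rng):
        pts = rng.normal(size=(10, 2))
        volume, flag = functional_richness(pts, 2)
        assert flag is None
        assert volume == pytest.approx(shoelace_area(pts), abs=1e-9)

    def test_one_dimensional_range(self):
        volume, flag = functional_richness(np.array([[1.0], [4.0], [2.0]]), 1)
        assert volume == pytest.approx(3.0) and flag is None

    def test_monotone_under_species_addition(self, rng):
        pts = rng.normal(size=(8, 3))
        v0, _ = functional_richness(pts, 3)
        v1, _ = functional_richness(np.vstack([pts, rng.normal(size=(1, 3))]), 3)
        assert v1 >= v0 - 1e-12

    def test_duplicate_point_changes_nothing(self, rng):
        pts = rng.normal(size=(6, 2))
        v0, _ = functional_richness(pts, 2)
        v1, _ = functional_richness(np.vstack([pts, pts[2]]), 2)
        assert v1 == pytest.approx(v0, abs=1e-12)


class TestStandardizeFric:
    def test_full_pool_is_one(self):
        assert standardize_fric(0.37, 0.37) == pytest.approx(1.0)

    def test_half_volume(self):
        assert standardize_fric(0.5, 1.0) == 0.5

    def test_zero_volume_subset(self):
        assert standardize_fric(0.0, 2.0) == 0.0

    def test_zero_global_rejected(self):
        with pytest.raises(ValueError):
            standardize_fric(0.1, 0.0)


class TestFunctionalEvenness:
    def test_equally_spaced_equal_weights(self):
        pts = np.arange(5, dtype=float)[:, None]
        value, flag = functional_evenness(pts, np.ones(5))
        assert value == pytest.approx(1.0) and flag is None

    def test_hand_computed_two_branch_case(self):
        # collinear species at 0, 9, 10 with equal weights: branch lengths
        # 9 and 1 give PEW = (0.9, 0.1) and FEve = (0.6 - 0.5)/(1 - 0.5)
        pts = np.array([[0.0], [9.0], [10.0]])
        value, flag = functional_evenness(pts, np.ones(3))
        assert value == pytest.approx(0.2) and flag is None

    def test_concentrated_weight_lowers_feve(self):
        angles = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        pts = np.c_[np.cos(angles), np.sin(angles)]
        value, _ = functional_evenness(pts, np.array([0.9, 0.05, 0.05]))
        assert value < 1.0

    def test_too_few_species(self):
        value, flag = functional_evenness(np.zeros((2, 2)), np.ones(2))
        assert np.isnan(value) and flag == "feve-needs-3-species"

    def test_matches_networkx_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(12, 3))
            w = rng.uniform(0.1, 1.0, size=12)
            value, flag = functional_evenness(pts, w)
            assert flag is None
            assert value == pytest.approx(brute_feve(pts, w), abs=1e-9)


class TestMST:
    def test_matches_scipy_total_weight(self, rng):
        from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst
        from scipy.spatial.distance import pdist, squareform
        pts = rng.normal(size=(15, 4))
        ours = sum(d for _, _, d in minimum_spanning_tree_edges(pts))
        ref = scipy_mst(squareform(pdist(pts))).sum()
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_lexicographic_tie_break(self):
        # four corners of a square: four shortest edges tie at length 1;
        # (0,1), (0,2) and (1,3) come first in (d, i, j) order
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        edges = [(i, j) for i, j, _ in minimum_spanning_tree_edges(pts)]
        assert edges == [(0, 1), (0, 2), (1, 3)]


class TestFunctionalDivergence:
    def test_regular_polygon_any_weights(self, rng):
        angles = np.linspace(0, 2 * np.pi, 7, endpoint=False)
        pts = np.c_[np.cos(angles), np.sin(angles)]
        value, flag = functional_divergence(pts, rng.uniform(0.1, 1, size=7))
        assert value == pytest.approx(1.0) and flag is None

    def test_weight_on_central_species_lowers_fdiv(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.45]])
        near, _ = functional_divergence(pts, np.array([0.01, 0.01, 0.01, 0.01, 1.0]))
        far, _ = functional_divergence(pts, np.array([1.0, 1.0, 1.0, 1.0, 0.01]))
        assert near < 0.5 < far

    def test_degenerate_hull_flagged(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        value, flag = functional_divergence(pts, np.ones(3))
        assert np.isnan(value) and flag == "fdiv-degenerate-hull"

    def test_matches_lp_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(10, 2))
            w = rng.uniform(0.1, 1, size=10)
            value, flag = functional_divergence(pts, w)
            assert flag is None
            assert value == pytest.approx(brute_fdiv(pts, w), abs=1e-9)


class TestFunctionalDispersion:
    def test_single_species(self):
        assert functional_dispersion(np.array([[2.0, 3.0]]), np.array([1.0])) == 0.0

    def test_equal_weight_pair(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        assert functional_dispersion(pts, np.ones(2)) == pytest.approx(2.5)

    def test_unequal_pair_hand_computed(self):
        pts = np.array([[0.0], [1.0]])
        assert functional_dispersion(pts, np.array([3.0, 1.0])) == pytest.approx(0.375)

    def test_rigid_motion_invariance_and_scaling(self, rng):
        pts = rng.normal(size=(9, 2))
        w = rng.uniform(0.1, 1, size=9)
        base = functional_dispersion(pts, w)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        assert functional_dispersion(pts @ rot.T + 5.0, w) == pytest.approx(base)
        assert functional_dispersion(3.0 * pts, w) == pytest.approx(3 * base)

    def test_matches_direct_oracle(self, rng):
        pts = rng.normal(size=(11, 4))
        w = rng.uniform(0, 1, size=11)
        w[0] = 0.0
        assert functional_dispersion(pts, w) == pytest.approx(
            brute_fdis(pts, w), abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(0, 10_000))
def test_feve_fdiv_bounded_on_random_configurations(seed):
    """FEve and FDiv stay in [0, 1] over random weighted point clouds."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 15))
    m = int(rng.integers(2, 4))
    pts = rng.normal(size=(n, m))
    w = rng.uniform(0.0, 1.0, size=n)
    w[rng.integers(n)] = 1.0  # ensure a positive weight
    feve, _ = functional_evenness(pts, w)
    fdiv, _ = functional_divergence(pts, w)
    assert -1e-12 <= feve <= 1 + 1e-12
    if not np.isnan(fdiv):
        assert -1e-12 <= fdiv <= 1 + 1e-12


class TestComputeFD:
    def test_full_pool_equal_weights(self, pool20):
        aw = AssemblageWeights(pool20.species, np.ones(20))
        result = compute_fd(pool20, aw, "combined", "all")
        assert result.fric_std == pytest.approx(1.0)
        assert result.nbsp == 20 and result.sing_sp == 20
        assert 0 <= result.quali_fric <= 1

    def test_identical_trait_species(self, schema):
        from traitdiv import ScenarioConfig, code_traits, generate_species_pool
        records = generate_species_pool(
            ScenarioConfig(n_species=10, n_profiles=1, seed=3), schema)
        pool = code_traits(records, schema)
        aw = AssemblageWeights(pool.species, np.ones(10))
        result = compute_fd(pool, aw, "combined", "degen")
        assert result.fdis == 0.0 and result.sing_sp == 1
        assert "fric-degenerate" in result.flags

    def test_equal_weights_fdis_is_mean_distance_to_centroid(self, pool20):
        aw = AssemblageWeights(pool20.species, np.ones(20))
        space = PooledSpace.build(pool20, "combined")
        result = compute_fd(pool20, aw, "combined", "all", space=space)
        centroid = space.coords.mean(axis=0)
        expected = np.mean(np.linalg.norm(space.coords - centroid, axis=1))
        assert result.fdis == pytest.approx(expected, abs=1e-12)

    def test_all_metrics_match_oracles_on_fixture(self, pool20, rng):
        """Step-by-step oracle equality for every metric on a 20-species
        assemblage with skewed weights, in the pooled reduced space."""
        space = PooledSpace.build(pool20, "feeding")
        weights = rng.uniform(0.0, 1.0, size=20)
        weights[5] = 0.0
        weights[7] = 1.0
        aw = AssemblageWeights(pool20.species, weights)
        result = compute_fd(pool20, aw, "feeding", "fix", space=space)
        pts = space.coords
        from oracles import simplex_volume_hull
        assert result.fric_raw == pytest.approx(simplex_volume_hull(pts), abs=1e-9)
        assert result.feve == pytest.approx(brute_feve(pts, weights), abs=1e-9)
        assert result.fdiv == pytest.approx(brute_fdiv(pts, weights), abs=1e-9)
        assert result.fdis == pytest.approx(brute_fdis(pts, weights), abs=1e-9)

    def test_subset_assemblage(self, pool20, rng):
        keep = list(pool20.species[:12])
        aw = AssemblageWeights(tuple(keep), rng.uniform(0.1, 1, size=12))
        result = compute_fd(pool20, aw, "combined", "subset")
        assert result.nbsp == 12
        assert 0 <= result.fric_std <= 1

    def test_unknown_species_rejected(self, pool20):
        aw = AssemblageWeights(("nope",), np.ones(1))
        with pytest.raises(ValueError, match="not in pool"):
            compute_fd(pool20, aw, "combined")
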
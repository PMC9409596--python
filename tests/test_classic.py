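from itertools import combinations

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst
from scipy.spatial.distance import pdist, squareform

from fdsweep import (
    CentroidGeometry,
    DistanceMatrix,
    functional_dispersion,
    functional_divergence,
    functional_evenness,
    functional_richness,
    minimum_spanning_tree,
    raos_q,
)


def _dm(points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] == 1 or points.ndim == 1:
        points = points.reshape(len(points), -1)
    d = squareform(pdist(points)) if len(points) > 1 else np.zeros((1, 1))
    return DistanceMatrix([f"s{i}" for i in range(len(points))], d)


def _exhaustive_mst_length(d: np.ndarray) -> float:
    """Brute-force minimum over all spanning trees (feasible for n <= 7)."""
    n = d.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for tree in combinations(edges, n - 1):
        # connectivity check by union-find
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for i, j in tree:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if ok:
            best = min(best, sum(d[i, j] for i, j in tree))
    return best


class TestMinimumSpanningTree:
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_total_length_matches_exhaustive_minimum(self, rng, n):
        d = _dm(rng.normal(size=(n, 2)))
        tree = minimum_spanning_tree(d)
        assert len(tree.branches) == n - 1
        assert tree.total_length == pytest.approx(
            _exhaustive_mst_length(d.values), abs=1e-12
        )

    def test_total_length_matches_scipy(self, rng):
        d = _dm(rng.normal(size=(10, 3)))
        tree = minimum_spanning_tree(d)
        assert tree.total_length == pytest.approx(
            scipy_mst(d.values).sum(), abs=1e-10
        )

    def test_deterministic_under_ties(self):
        # four corners of a square: several MSTs share the minimum length
        d = _dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        t1 = minimum_spanning_tree(d)
        t2 = minimum_spanning_tree(d)
        assert t1.branches == t2.branches


class TestFunctionalRichness:
    def test_unit_square_area_one(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert functional_richness(pts, dims=2) == pytest.approx(1.0)

    def test_collinear_points_undefined(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        assert np.isnan(functional_richness(pts, dims=2))

    def test_too_few_species_undefined_not_zero(self):
        pts = np.array([[0, 0], [1, 1]], dtype=float)
        assert np.isnan(functional_richness(pts, dims=2))

    def test_matches_shoelace_oracle(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.normal(size=(6, 2))
        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
        )
        assert functional_richness(pts, dims=2) == pytest.approx(
            shoelace, abs=1e-9
        )

    def test_monotone_under_species_addition(self, rng):
        pts = rng.normal(size=(12, 2))
        vols = [functional_richness(pts[:n], dims=2) for n in (4, 6, 9, 12)]
        vols = [v for v in vols if not np.isnan(v)]
        assert all(b >= a - 1e-12 for a, b in zip(vols, vols[1:]))


class TestFunctionalEvenness:
    def test_perfectly_even_community_is_one(self):
        d = _dm(np.array([[0.0], [1.0], [2.0]]))
        tree = minimum_spanning_tree(d)
        a = np.full(3, 1 / 3)
        assert functional_evenness(tree, a) == pytest.approx(1.0)

    def test_hand_computed_uneven_case(self):
        # positions 0, 1, 10, equal abundance: PEW = (0.1, 0.9) -> 0.2
        d = _dm(np.array([[0.0], [1.0], [10.0]]))
        tree = minimum_spanning_tree(d)
        a = np.full(3, 1 / 3)
        assert functional_evenness(tree, a) == pytest.approx(0.2)

    def test_concentrated_branch_limit_approaches_zero(self):
        # one branch takes nearly all partial weighted evenness
        d = _dm(np.array([[0.0], [1e-6], [1.0]]))
        tree = minimum_spanning_tree(d)
        a = np.full(3, 1 / 3)
        assert functional_evenness(tree, a) == pytest.approx(0.0, abs=1e-5)

    def test_fewer_than_three_species_undefined(self):
        d = _dm(np.array([[0.0], [1.0]]))
        tree = minimum_spanning_tree(d)
        assert np.isnan(functional_evenness(tree, np.array([0.5, 0.5])))

    def test_bounded_zero_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            d = _dm(rng.normal(size=(n, 2)))
            a = rng.dirichlet(np.ones(n))
            v = functional_evenness(minimum_spanning_tree(d), a)
            assert -1e-12 <= v <= 1 + 1e-12


class TestFunctionalDispersion:
    def test_single_species_zero(self):
        assert functional_dispersion(np.array([[1.0, 2.0]]), np.array([1.0])) == 0.0

    def test_two_species_equal_abundance(self):
        x = np.array([[0.0], [1.0]])
        assert functional_dispersion(x, np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_two_species_skewed_abundance(self):
        x = np.array([[0.0], [1.0]])
        a = np.array([0.9, 0.1])
        # centroid at 0.1: 0.9*0.1 + 0.1*0.9
        assert functional_dispersion(x, a) == pytest.approx(0.18)

    def test_accepts_distance_matrix(self, rng):
        pts = rng.normal(size=(6, 2))
        a = rng.dirichlet(np.ones(6))
        direct = functional_dispersion(pts, a)
        via_dm = functional_dispersion(_dm(pts), a)
        assert via_dm == pytest.approx(direct, abs=1e-8)

    def test_invariant_to_species_duplication(self, rng):
        pts = rng.normal(size=(5, 2))
        a = rng.dirichlet(np.ones(5))
        pts2 = np.vstack([pts, pts[0]])
        a2 = np.concatenate([a, [a[0] / 2]])
        a2[0] /= 2
        assert functional_dispersion(pts2, a2) == pytest.approx(
            functional_dispersion(pts, a), abs=1e-10
        )


class TestFunctionalDivergence:
    def test_equidistant_species_give_one(self):
        # equilateral triangle, any abundances: all z equal -> FDiv = 1
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        a = np.array([0.2, 0.3, 0.5])
        assert functional_divergence(pts, a) == pytest.approx(1.0)

    def test_hand_computed_geometry(self):
        geom = CentroidGeometry(
            centroid=np.zeros(1),
            z=np.array([1.0, 1.0, 4.0]),
            dG_bar=2.0,
            delta_d=0.0,
            delta_abs_d=4.0 / 3.0,
        )
        a = np.full(3, 1 / 3)
        assert functional_divergence(geom, a) == pytest.approx(0.6)

    def test_abundance_on_farthest_species_approaches_one(self):
        eps = 1e-4
        geom_a = np.array([eps / 2, eps / 2, 1 - eps])
        z = np.array([1.0, 1.0, 4.0])
        dg = 2.0
        geom = CentroidGeometry(
            centroid=np.zeros(1), z=z, dG_bar=dg,
            delta_d=float(geom_a @ (z - dg)),
            delta_abs_d=float(geom_a @ np.abs(z - dg)),
        )
        assert functional_divergence(geom, geom_a) == pytest.approx(1.0, abs=1e-3)

    def test_coincident_species_undefined(self):
        pts = np.zeros((3, 2))
        assert np.isnan(functional_divergence(pts, np.full(3, 1 / 3)))

    def test_bounded_zero_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            pts = rng.normal(size=(n, 2))
            a = rng.dirichlet(np.ones(n))
            v = functional_divergence(pts, a)
            assert -1e-12 <= v <= 1 + 1e-12


class TestRaosQ:
    def test_single_species_zero(self):
        assert raos_q(_dm(np.array([[0.0]])), np.array([1.0])) == 0.0

    def test_two_species_closed_form(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert raos_q(d, np.array([0.5, 0.5])) == pytest.approx(0.25)

    def test_matches_brute_force_double_loop(self, rng):
        pts = rng.normal(size=(4, 3))
        d = _dm(pts)
        p = rng.dirichlet(np.ones(4))
        brute = sum(
            d.values[i, j] * p[i] * p[j]
            for i in range(4) for j in range(i + 1, 4)
        )
        assert raos_q(d, p) == pytest.approx(brute, abs=1e-12)

    def test_permutation_invariance(self, rng):
        pts = rng.normal(size=(6, 2))
        p = rng.dirichlet(np.ones(6))
        d = _dm(pts)
        perm = rng.permutation(6)
        d2 = DistanceMatrix(
            [d.species[i] for i in perm], d.values[np.ix_(perm, perm)]
        )
        assert raos_q(d2, p[perm]) == pytest.approx(raos_q(d, p), abs=1e-14)

    def test_invariant_to_species_duplication(self, rng):
        pts = rng.normal(size=(5, 2))
        p = rng.dirichlet(np.ones(5))
        d = _dm(pts)
        pts2 = np.vstack([pts, pts[0]])
        p2 = np.concatenate([p, [p[0] / 2]])
        p2[0] /= 2
        assert raos_q(_dm(pts2), p2) == pytest.approx(raos_q(d, p), abs=1e-12)

    def test_rejects_unnormalised_abundances(self):
        d = _dm(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError, match="sum to 1"):
            raos_q(d, np.array([0.5, 0.2]))
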
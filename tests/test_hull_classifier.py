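import numpy as np
import pytest

from structsep.hull_classifier import (
    HullMembership,
    hull_rates,
    hull_rates_by_block,
    in_hull,
    membership_matrix,
)
from structsep.feature_table import FeatureMatrix

from oracles import convex_polygon_contains, facet_hull_contains

TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


class TestInHull:
    def test_interior_point(self):
        assert in_hull([0.25, 0.25], TRIANGLE)

    def test_exterior_point(self):
        assert not in_hull([1.0, 1.0], TRIANGLE)

    def test_boundary_point_counts_as_inside(self):
        assert in_hull([0.5, 0.5], TRIANGLE)  # on the hypotenuse
        assert in_hull([0.0, 0.0], TRIANGLE)  # a vertex

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            in_hull([0.1, 0.1, 0.1], TRIANGLE)

    def test_single_generator_is_a_point_hull(self):
        assert in_hull([1.0, 2.0], np.array([[1.0, 2.0]]))
        assert not in_hull([1.0, 2.1], np.array([[1.0, 2.0]]))

    def test_degenerate_segment_in_3d(self):
        seg = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        assert in_hull([0.5, 0.5, 0.5], seg)
        assert not in_hull([0.5, 0.5, 0.6], seg)

    def test_agrees_with_2d_polygon_oracle(self, rng):
        from scipy.spatial import ConvexHull

        generators = rng.normal(size=(25, 2))
        hull = ConvexHull(generators)
        polygon = generators[hull.vertices]  # counterclockwise
        for _ in range(200):
            q = rng.normal(scale=1.2, size=2)
            assert in_hull(q, generators, tol=1e-9) == convex_polygon_contains(
                q, polygon, tol=1e-9
            )

    def test_agrees_with_3d_facet_oracle(self, rng):
        generators = rng.normal(size=(40, 3))
        for _ in range(200):
            q = rng.normal(scale=1.2, size=3)
            assert in_hull(q, generators, tol=1e-9) == facet_hull_contains(
                q, generators, tol=1e-9
            )

    def test_tolerance_monotone_near_boundary(self, rng):
        generators = rng.normal(size=(20, 2))
        from scipy.spatial import ConvexHull

        polygon = generators[ConvexHull(generators).vertices]
        center = polygon.mean(axis=0)
        checked = 0
        for i in range(100):
            # points just outside the boundary, scaled slightly beyond a vertex
            v = polygon[i % len(polygon)]
            q = center + (v - center) * (1.0 + 1e-6)
            tols = [0.0, 1e-9, 1e-6, 1e-3, 1.0]
            answers = [in_hull(q, generators, t) for t in tols]
            # once inside at some tolerance, stays inside at looser ones
            assert answers == sorted(answers)
            checked += 1
        assert checked == 100


class TestMembershipMatrix:
    def test_far_separated_clusters_only_own_class(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (15, 3)), rng.normal(50, 0.5, (15, 3))])
        labels = ["a"] * 15 + ["b"] * 15
        mem = membership_matrix(X, labels)
        expected = np.zeros((30, 2), dtype=bool)
        expected[:15, 0] = True
        expected[15:, 1] = True
        np.testing.assert_array_equal(mem.matrix, expected)

    def test_own_class_membership_by_construction(self, rng):
        X = rng.normal(size=(20, 4))
        labels = list(rng.choice(["a", "b"], size=18)) + ["a", "b"]
        mem = membership_matrix(X, labels)
        for i, lab in enumerate(labels):
            assert mem.matrix[i, mem.class_order.index(lab)]

    def test_nested_class_is_member_of_both(self, rng):
        outer = rng.normal(size=(30, 2)) * 10
        inner = rng.normal(size=(10, 2)) * 0.01
        X = np.vstack([outer, inner])
        labels = ["A"] * 30 + ["B"] * 10
        mem = membership_matrix(X, labels)
        assert mem.matrix[30:, 0].all()  # B points inside A's hull
        assert mem.matrix[30:, 1].all()

    def test_matches_per_point_feasibility_oracle(self, rng):
        X = rng.normal(size=(24, 4))
        labels = list(np.repeat(["a", "b", "c"], 8))
        mem = membership_matrix(X, labels, tol=1e-8)
        lab_arr = np.asarray(labels)
        for j, cls in enumerate(mem.class_order):
            G = X[lab_arr == cls]
            for i in range(24):
                assert mem.matrix[i, j] == in_hull(X[i], G, tol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            membership_matrix(rng.normal(size=(5, 2)), ["a"] * 5)


class TestHullRates:
    def test_disjoint_clusters_are_fully_exclusive(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (15, 3)), rng.normal(50, 0.5, (15, 3))])
        labels = ["a"] * 15 + ["b"] * 15
        table = hull_rates(membership_matrix(X, labels))
        assert [r.rate_percent for r in table.rates] == [100.0, 100.0]

    def test_nesting_zeroes_the_inner_class(self, rng):
        outer = np.vstack([rng.normal(0, 10, (30, 2))])
        inner = rng.normal(size=(10, 2)) * 0.01
        X = np.vstack([outer, inner])
        labels = ["A"] * 30 + ["B"] * 10
        table = hull_rates(membership_matrix(X, labels))
        rates = {r.class_name: r.rate_percent for r in table.rates}
        assert rates["B"] == 0.0
        assert rates["A"] == 100.0  # A's spread points are not inside tiny B

    def test_exclusivity_counts_from_hand_built_membership(self):
        matrix = np.array(
            [
                [True, False],  # a, exclusive
                [True, True],  # a, shared -> not exclusive
                [False, True],  # b, exclusive
                [True, True],  # b, shared
            ]
        )
        mem = HullMembership(matrix, ["a", "b"], ["a", "a", "b", "b"], tol=0.0)
        table = hull_rates(mem)
        assert [(r.numerator, r.denominator) for r in table.rates] == [(1, 2), (1, 2)]

    def test_affine_invariance_of_rates(self, rng):
        X = rng.normal(size=(30, 3))
        labels = list(np.repeat(["a", "b", "c"], 10))
        base = [
            (r.numerator, r.denominator)
            for r in hull_rates(membership_matrix(X, labels, tol=1e-7)).rates
        ]
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        t = rng.normal(size=3)
        mapped = [
            (r.numerator, r.denominator)
            for r in hull_rates(membership_matrix(X @ M + t, labels, tol=1e-7)).rates
        ]
        assert base == mapped


def test_blockwise_rates_one_table_per_block(rng):
    values = np.vstack([rng.normal(0, 1, (12, 25)), rng.normal(8, 1, (12, 25))])
    fm = FeatureMatrix.from_array(
        values,
        ids=[f"p{i}" for i in range(24)],
        columns=[f"c{i}" for i in range(25)],
        labels=["a"] * 12 + ["b"] * 12,
    )
    tables = hull_rates_by_block(fm, block_size=10)
    assert [t.block for t in tables] == ["B1", "B2", "B3"]
    assert all(t.classifier == "hull" for t in tables)
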
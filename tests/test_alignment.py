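"""Procrustes alignment, the stress measure, and hull summaries."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from attnspace import convex_hull_summary, procrustes_align, stress
from attnspace.errors import (
    DegenerateConfigurationError,
    DegenerateHullError,
    UndefinedStressError,
)

TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


def _stress_oracle(X, Y):
    """Direct double-loop evaluation of the normalized stress formula."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    d1, d2 = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d1.append(np.linalg.norm(X[i] - X[j]))
            d2.append(np.linalg.norm(Y[i] - Y[j]))
    d1, d2 = np.array(d1), np.array(d2)
    return np.sum((d1 - d2) ** 2) / np.sum((d1 - d1.mean()) ** 2)


def _rot(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


class TestStress:
    def test_identical_configurations(self):
        assert stress(TRIANGLE, TRIANGLE) == 0.0

    def test_doubled_configuration_frozen_value(self):
        # distances {1,1,sqrt2} vs {2,2,2sqrt2}: numerator 4, denominator
        # 2*(1-m)^2+(sqrt2-m)^2 with m=(2+sqrt2)/3 ~ 0.114381
        val = stress(TRIANGLE, 2 * TRIANGLE)
        m = (2 + np.sqrt(2)) / 3
        denom = 2 * (1 - m) ** 2 + (np.sqrt(2) - m) ** 2
        assert val == pytest.approx(4.0 / denom, rel=1e-12)
        assert val == pytest.approx(34.97, abs=0.01)

    def test_vs_equilateral_frozen_value(self):
        eq = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        val = stress(TRIANGLE, eq)
        m = (2 + np.sqrt(2)) / 3
        denom = 2 * (1 - m) ** 2 + (np.sqrt(2) - m) ** 2
        assert val == pytest.approx((np.sqrt(2) - 1) ** 2 / denom, rel=1e-12)
        assert val == pytest.approx(1.5001, abs=0.001)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 2))
        Y = rng.normal(size=(7, 2))
        assert stress(X, Y) == pytest.approx(_stress_oracle(X, Y), abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        Y = rng.normal(size=(6, 2))
        moved = Y @ _rot(90).T + np.array([3.0, -1.0])
        assert stress(X, moved) == pytest.approx(stress(X, Y), abs=1e-10)

    def test_asymmetry_of_the_normalization(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        Y = 0.2 * rng.normal(size=(5, 2))
        assert stress(X, Y) != pytest.approx(stress(Y, X), rel=1e-3)

    def test_equal_distances_rejected(self):
        eq = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        with pytest.raises(UndefinedStressError):
            stress(eq, TRIANGLE)


class TestProcrustes:
    def test_identity(self):
        res = procrustes_align(TRIANGLE, TRIANGLE.copy(), allow_scaling=True)
        assert res.stress == pytest.approx(0.0, abs=1e-12)
        assert res.scale == pytest.approx(1.0)
        assert np.allclose(res.aligned_config_2, TRIANGLE, atol=1e-12)

    def test_scaling_removes_magnification(self):
        res = procrustes_align(TRIANGLE, 2 * TRIANGLE, allow_scaling=True)
        assert res.scale == pytest.approx(0.5)
        assert res.stress == pytest.approx(0.0, abs=1e-12)

    def test_scaling_off_retains_magnification(self):
        res = procrustes_align(TRIANGLE, 2 * TRIANGLE, allow_scaling=False)
        assert res.scale == 1.0
        assert res.stress == pytest.approx(stress(TRIANGLE, 2 * TRIANGLE),
                                           rel=1e-12)

    def test_similarity_transform_fully_removed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        Y = 3.0 * (X @ _rot(123).T) + np.array([5.0, -2.0])
        Y = Y @ np.diag([1.0, -1.0])  # reflection is allowed too
        res = procrustes_align(X, Y, allow_scaling=True)
        assert res.stress == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.aligned_config_2, X, atol=1e-8)

    def test_alignment_is_least_squares_optimal(self):
        """Brute-force oracle over rotation angle x scale for a 2-D pair."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        Y = rng.normal(size=(6, 2))
        res = procrustes_align(X, Y, allow_scaling=True)
        best = np.inf
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        for deg in np.arange(0, 360, 0.25):
            for refl in (1.0, -1.0):
                R = _rot(deg) @ np.diag([1.0, refl])
                s = np.trace(Xc.T @ (Yc @ R)) / np.sum(Yc ** 2)
                best = min(best, np.sum((Xc - s * Yc @ R) ** 2))
        ours = np.sum((res.aligned_config_2 - X) ** 2)
        assert ours <= best + 1e-6

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            procrustes_align(TRIANGLE, np.ones((3, 2)))


class TestConvexHull:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        area, radius = convex_hull_summary(square)
        assert area == pytest.approx(1.0)
        assert radius == pytest.approx(np.sqrt(2) / 2)

    def test_regular_octagon_on_unit_circle(self):
        a = np.deg2rad(np.arange(8) * 45.0)
        pts = np.column_stack([np.cos(a), np.sin(a)])
        area, radius = convex_hull_summary(pts)
        assert area == pytest.approx(2 * np.sqrt(2), rel=1e-12)
        assert radius == pytest.approx(1.0)

    def test_homogeneity_under_scaling(self, rng):
        pts = rng.normal(size=(8, 2))
        a1, r1 = convex_hull_summary(pts)
        a2, r2 = convex_hull_summary(2 * pts)
        assert a2 == pytest.approx(4 * a1) and r2 == pytest.approx(2 * r1)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(DegenerateHullError):
            convex_hull_summary(line)
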
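"""GPA, Procrustes distance, TPS bending energy/warp, semilandmark sliding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from craniomod import gm
from craniomod.gm import LandmarkConfiguration, SlidingScheme

from conftest import random_triangle, rotation_grid_search_distance


def random_similarity(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    s = rng.uniform(0.2, 5.0)
    t = rng.normal(scale=10, size=3)
    return lambda pts: s * pts @ R.T + t


class TestCentroidSize:
    def test_square_example(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert gm.centroid_size(pts) == pytest.approx(2 * np.sqrt(2))

    def test_coincident_points_zero(self):
        assert gm.centroid_size(np.ones((5, 3))) == 0.0

    def test_homogeneity(self, rng):
        pts = rng.normal(size=(7, 3))
        assert gm.centroid_size(3.7 * pts) == pytest.approx(3.7 * gm.centroid_size(pts))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gm.centroid_size(np.empty((0, 3)))


class TestProcrustesDistance:
    def test_zero_for_similarity_transformed_copy(self, rng):
        pts = rng.normal(size=(6, 3))
        assert gm.procrustes_distance(pts, random_similarity(rng)(pts)) < 1e-9

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = (rng.normal(size=(5, 3)) for _ in range(3))
            dab = gm.procrustes_distance(a, b)
            assert dab == pytest.approx(gm.procrustes_distance(b, a), abs=1e-10)
            assert dab <= gm.procrustes_distance(a, c) + gm.procrustes_distance(c, b) + 1e-10

    def test_matches_rotation_grid_search_oracle(self, rng):
        """Planar triangles: SVD rotation equals brute-force angle search."""
        for _ in range(25):
            a = random_triangle(rng)
            b = random_triangle(rng)
            oracle, _ = rotation_grid_search_distance(a, b, step=1e-4)
            assert gm.procrustes_distance(a, b) == pytest.approx(oracle, abs=1e-4)

    def test_k_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            gm.procrustes_distance(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))

    def test_batched_matches_scalar(self, rng):
        a = rng.normal(size=(8, 6, 3))
        b = rng.normal(size=(8, 6, 3))
        batch = gm.batched_procrustes_distance(a, b)
        single = [gm.procrustes_distance(x, y) for x, y in zip(a, b)]
        np.testing.assert_allclose(batch, single, atol=1e-10)


class TestGPA:
    def test_rotated_translated_copy_aligns_exactly(self, rng):
        pts = rng.normal(size=(6, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        res = gm.gpa([pts, pts @ Rz.T + np.array([5.0, -2.0, 1.0])])
        assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-8
        assert gm.procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-8

    def test_already_aligned_converges_immediately(self, rng):
        base = gm.to_shape(rng.normal(size=(7, 3)))
        res1 = gm.gpa([base + rng.normal(scale=0.01, size=(7, 3)) for _ in range(4)])
        res2 = gm.gpa(list(res1.aligned))
        assert res2.iterations == 1
        assert np.abs(res2.aligned - res1.aligned).max() < 1e-6

    def test_invariance_under_similarity_transforms(self, rng):
        configs = [rng.normal(size=(8, 3)) for _ in range(6)]
        res1 = gm.gpa(configs)
        res2 = gm.gpa([random_similarity(rng)(c) for c in configs])
        # the consensus is defined up to rotation: compare via Procrustes distance
        assert gm.procrustes_distance(res1.mean_shape, res2.mean_shape) < 1e-6
        d1 = [gm.procrustes_distance(a, res1.mean_shape) for a in res1.aligned]
        d2 = [gm.procrustes_distance(a, res2.mean_shape) for a in res2.aligned]
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_unit_sizes_and_recorded_sizes(self, rng):
        configs = [rng.normal(scale=s, size=(6, 3)) for s in (1, 2, 3)]
        res = gm.gpa(configs)
        for a in res.aligned:
            assert gm.centroid_size(a) == pytest.approx(1.0)
        assert gm.centroid_size(res.mean_shape) == pytest.approx(1.0)
        np.testing.assert_allclose(
            res.centroid_sizes, [gm.centroid_size(c) for c in configs]
        )

    def test_mean_optimality(self, rng):
        """Summed squared distances to the consensus beat any single specimen."""
        res = gm.gpa([rng.normal(size=(7, 3)) for _ in range(8)])
        to_mean = sum(gm.procrustes_distance(a, res.mean_shape) ** 2 for a in res.aligned)
        for target in res.aligned:
            to_target = sum(gm.procrustes_distance(a, target) ** 2 for a in res.aligned)
            assert to_mean <= to_target + 1e-9

    def test_k_mismatch_and_degenerate_errors(self, rng):
        with pytest.raises(ValueError):
            gm.gpa([rng.normal(size=(5, 3)), rng.normal(size=(6, 3))])
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            gm.gpa([line, rng.normal(size=(5, 3))])


class TestBendingEnergy:
    def test_affine_and_identity_deformations_have_zero_energy(self, rng):
        ref = rng.normal(size=(8, 3))
        assert gm.tps_bending_energy(ref, ref) < 1e-8            # identity
        aff = ref @ rng.normal(size=(3, 3)) + rng.normal(size=3)
        assert abs(gm.tps_bending_energy(ref, aff)) < 1e-8       # affine null space

    def test_psd_quadratic_form(self, rng):
        ref = rng.normal(size=(9, 3))
        B = gm.tps_bending_energy_matrix(ref)
        w = np.linalg.eigvalsh(B)
        assert w.min() > -1e-9

    def test_coincident_points_error(self):
        ref = np.zeros((6, 3))
        ref[1:] = np.arange(15).reshape(5, 3)
        ref[2] = ref[1]
        with pytest.raises(ValueError, match="singular|coincident"):
            gm.tps_bending_energy_matrix(ref)

    def test_matches_numerical_integral_of_tps_functional(self, rng):
        """8*pi*y'By equals the integral of squared second derivatives.

        Oracle: the interpolant's Laplacian is a sum of point sources
        2*w_i/r_i, and the bending functional equals the integral of its
        square; that integral is evaluated by midpoint quadrature with
        analytic corrections inside small balls around the landmarks
        (where the smooth remainder is harmonic).
        """
        ref = rng.uniform(-1, 1, (6, 3))
        from craniomod.gm import _tps_system

        for trial in range(2):
            y = np.zeros(6)
            if trial == 0:
                y[2] = 1.0                      # single-point displacement
            else:
                y = rng.normal(size=6)
            quad = float(y @ gm.tps_bending_energy_matrix(ref) @ y)
            coef = np.linalg.solve(_tps_system(ref), np.concatenate([y, np.zeros(4)]))
            w = coef[:6]
            oracle = _integral_of_squared_laplacian(ref, w, box=10.0, n=250, delta=0.3)
            assert oracle == pytest.approx(8 * np.pi * quad, rel=0.02)


def _integral_of_squared_laplacian(pts, w, box, n, delta):
    """4 * integral of (sum_i w_i / r_i)^2 over R^3, by excluded-ball midpoint
    quadrature plus analytic ball corrections (the remainder s = sum_{j!=i}
    w_j/r_j is harmonic at p_i, so its Laplacian term vanishes)."""
    k = len(pts)
    h = 2 * box / n
    ax = -box + h * (np.arange(n) + 0.5)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    tot = 0.0
    for z in ax:
        g = np.zeros(X.size)
        mind2 = np.full(X.size, np.inf)
        for i in range(k):
            d2 = (X.ravel() - pts[i, 0]) ** 2 + (Y.ravel() - pts[i, 1]) ** 2 + (z - pts[i, 2]) ** 2
            mind2 = np.minimum(mind2, d2)
            g += w[i] / np.sqrt(d2)
        keep = mind2 > delta**2
        tot += (g[keep] ** 2).sum() * h**3
    for i in range(k):
        d = pts - pts[i]
        r = np.linalg.norm(d, axis=1)
        r[i] = np.inf
        s0 = (w / r).sum()
        g1 = -(w[:, None] * d / r[:, None] ** 3).sum(axis=0)
        tot += (
            4 * np.pi * w[i] ** 2 * delta
            + 2 * w[i] * s0 * 2 * np.pi * delta**2
            + s0**2 * (4 / 3) * np.pi * delta**3
            + g1 @ g1 * 4 * np.pi * delta**5 / 15
        )
    return 4 * tot


class TestTpsWarp:
    def test_identity_and_landmark_interpolation(self, rng):
        src = rng.normal(size=(7, 3))
        q = rng.normal(size=(11, 3))
        np.testing.assert_allclose(gm.tps_warp(src, src, q), q, atol=1e-9)
        tgt = src + rng.normal(scale=0.3, size=(7, 3))
        np.testing.assert_allclose(gm.tps_warp(src, tgt, src), tgt, atol=1e-8)

    def test_affine_exactness(self, rng):
        src = rng.normal(size=(6, 3))
        A, b = rng.normal(size=(3, 3)), rng.normal(size=3)
        q = rng.normal(size=(20, 3))
        np.testing.assert_allclose(gm.tps_warp(src, src @ A + b, q), q @ A + b, atol=1e-8)


class TestSliding:
    def make_cohort(self, rng, n=5, k=10, n_slide=4, scale=0.05):
        base = gm.to_shape(rng.normal(size=(k, 3)))
        shapes = np.stack([gm.to_shape(base + rng.normal(scale=scale, size=(k, 3)))
                           for _ in range(n)])
        neighbors = {i: (i - 1, i + 1) for i in range(k - n_slide - 1, k - 1)}
        return shapes, SlidingScheme(curve_neighbors=neighbors), base

    def test_reference_configuration_does_not_move(self, rng):
        shapes, scheme, base = self.make_cohort(rng)
        slid, e0, e1 = gm.slide_against_reference(base.copy(), scheme, base)
        np.testing.assert_allclose(slid, base, atol=1e-8)

    def test_energy_never_increases(self, rng):
        for _ in range(10):
            shapes, scheme, base = self.make_cohort(rng)
            _, e0, e1 = gm.slide_against_reference(shapes, scheme, base)
            assert np.all(e1 <= e0 + 1e-12)

    def test_fixed_landmarks_unmoved(self, rng):
        shapes, scheme, base = self.make_cohort(rng)
        slid, _, _ = gm.slide_against_reference(shapes, scheme, base)
        sliding = scheme.sliding_indices
        fixed = [i for i in range(shapes.shape[1]) if i not in sliding]
        np.testing.assert_allclose(slid[:, fixed], shapes[:, fixed], atol=1e-12)

    def test_collinear_midpoint_oracle(self):
        """One curve semilandmark between two fixed points on a line.

        With the reference equally spaced, minimizing the bending penalty
        along the sliding line is a 1D quadratic whose optimum puts the
        point back at the reference position (here: the midpoint).
        """
        ref = np.array(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0], [1, 3, 1]], float
        )
        config = ref.copy()
        config[1] = [1.4, 0, 0]  # displaced along the line through its neighbors
        scheme = SlidingScheme(curve_neighbors={1: (0, 2)})
        slid, e0, e1 = gm.slide_against_reference(config, scheme, ref)
        assert e1 <= e0
        # closed-form 1D minimization along the tangent direction
        B = gm.tps_bending_energy_matrix(ref)
        t_grid = np.linspace(-1.0, 1.0, 20001)
        best = None
        for t in t_grid:
            y = config.copy()
            y[1, 0] += t
            e = float(np.einsum("kd,kj,jd->", y, B, y))
            if best is None or e < best[1]:
                best = (t, e)
        assert slid[1, 0] == pytest.approx(config[1, 0] + best[0], abs=1e-3)
        assert slid[1, 0] == pytest.approx(1.0, abs=1e-6)  # back to the midpoint

    def test_surface_semilandmark_stays_in_tangent_plane(self, rng):
        # points on z=0 plane; surface point must only move within the plane
        k = 12
        pts = np.column_stack([rng.normal(size=(k, 2)), np.zeros(k)])
        pts[0, 2] = 1e-6  # break exact coplanarity of the TPS system
        ref = pts + rng.normal(scale=0.01, size=(k, 3)) * np.array([1, 1, 0])
        scheme = SlidingScheme(surface_points=[5])
        slid, _, _ = gm.slide_against_reference(pts, scheme, ref)
        assert abs(slid[5, 2] - pts[5, 2]) < 1e-6

    def test_coincident_neighbors_error(self, rng):
        shapes, _, base = self.make_cohort(rng)
        shapes[0, 3] = shapes[0, 4]
        scheme = SlidingScheme(curve_neighbors={5: (3, 4)})
        with pytest.raises(ValueError, match="point 5"):
            gm.slide_against_reference(shapes[0], scheme, base)

    def test_outer_loop_converges_and_reduces_energy(self, rng):
        shapes, scheme, base = self.make_cohort(rng, n=6)
        configs = [
            LandmarkConfiguration(specimen_id=f"s{i}", region="maxilla", points=20 * s)
            for i, s in enumerate(shapes)
        ]
        slid, res = gm.slide_semilandmarks(configs, scheme)
        assert res.converged
        # energy against the final mean: slid cohort at most the unslid one
        B = gm.tps_bending_energy_matrix(res.mean_shape)
        raw = gm.gpa(configs).aligned
        e_slid = sum(float(np.einsum("kd,kj,jd->", y, B, y)) for y in slid)
        e_raw = sum(float(np.einsum("kd,kj,jd->", y, B, y)) for y in raw)
        assert e_slid <= e_raw + 1e-10
        np.testing.assert_allclose(res.centroid_sizes, 20.0, rtol=1e-12)
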
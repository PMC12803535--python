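import numpy as np
import pytest

from craniomod.synthetic import CohortSpec, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, quiet cohort reused by read-only tests."""
    spec = CohortSpec(
        n_per_age_group=(3, 4, 4, 3, 3),
        n_landmarks=6,
        n_semilandmarks=8,
        n_cells=24,
        noise_sd_shape=0.5,
        missing_rate=0.05,
        seed=11,
    )
    return generate_cohort(spec)


def random_triangle(rng, planar=True):
    """A non-degenerate triangle; planar ones live in the z=0 plane."""
    while True:
        pts = rng.normal(size=(3, 3))
        if planar:
            pts[:, 2] = 0.0
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered) >= 2 and np.linalg.norm(centered) > 0.1:
            return pts


def rotation_grid_search_distance(a, b, step=1e-4):
    """Brute-force partial Procrustes distance for planar (z=0) shapes.

    Scans in-plane rotation angles at ``step`` rad resolution.  Proper 3D
    rotations that keep the z=0 plane invariant are the in-plane rotations
    plus each composed with a half-turn about an in-plane axis (which acts
    on the plane as a reflection), so both branches are scanned.
    Returns (best_distance, best_angle).
    """
    from craniomod.gm import to_shape

    sa, sb = to_shape(a), to_shape(b)
    angles = np.arange(0.0, 2 * np.pi, step)
    c, s = np.cos(angles), np.sin(angles)
    best = np.inf
    best_angle = 0.0
    for flip in (1.0, -1.0):
        x, y = sa[:, 0], flip * sa[:, 1]
        rx = np.outer(c, x) - np.outer(s, y)      # (n_angles, k)
        ry = np.outer(s, x) + np.outer(c, y)
        d2 = ((rx - sb[:, 0]) ** 2).sum(axis=1) + ((ry - sb[:, 1]) ** 2).sum(axis=1)
        i = int(np.argmin(d2))
        if d2[i] < best:
            best, best_angle = float(d2[i]), float(angles[i])
    return float(np.sqrt(best)), best_angle
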
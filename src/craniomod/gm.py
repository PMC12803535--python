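"""Statistical shape analysis kernel.

Centroid size, generalized Procrustes analysis (GPA), Procrustes distance,
thin-plate-spline (TPS) bending energy and warping, and bending-energy-
minimizing semilandmark sliding, for 3D landmark configurations.

Conventions
-----------
* Partial Procrustes: configurations are centered and scaled to *unit
  centroid size*; the rotation solve forbids reflections (a reflected fit
  would merge antimeres).
* The TPS kernel is ``U(r) = -r`` (3D biharmonic convention), which makes
  the bending-energy matrix positive semidefinite so that sliding is a
  well-posed minimization.  The physical bending energy (the integral of
  squared second derivatives of the interpolant over R^3) equals
  ``8*pi`` times the quadratic form reported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

ROLES = ("fixed", "curve_semilandmark", "surface_semilandmark")


@dataclass
class LandmarkConfiguration:
    """One specimen's named 3D landmark + semilandmark coordinates.

    Parameters
    ----------
    specimen_id : str
    region : str
        Facial region the configuration samples (e.g. ``"maxilla"``).
    points : (k, 3) float array
        Cartesian coordinates in mm.
    labels : list of str
        Unique per-point names.
    roles : list of str
        Per-point role: ``fixed``, ``curve_semilandmark`` or
        ``surface_semilandmark``.
    """

    specimen_id: str
    region: str
    points: NDArray[np.float64]
    labels: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(
                f"points must be (k, 3); got {self.points.shape} "
                f"for specimen {self.specimen_id!r}"
            )
        k = len(self.points)
        if not self.labels:
            self.labels = [f"p{i}" for i in range(k)]
        if not self.roles:
            self.roles = ["fixed"] * k
        if len(self.labels) != k or len(self.roles) != k:
            raise ValueError("labels/roles length must match point count")
        if len(set(self.labels)) != k:
            raise ValueError("labels must be unique")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")

    @property
    def k(self) -> int:
        return len(self.points)


@dataclass
class SlidingScheme:
    """Which semilandmarks slide, and along what.

    ``curve_neighbors`` maps a curve-semilandmark index to its two distinct
    neighbor indices along the curve; the sliding direction is the neighbor
    chord.  ``surface_points`` slide in their local tangent plane, estimated
    from the ``n_neighbors`` nearest points unless explicit ``normals`` are
    supplied.
    """

    curve_neighbors: dict[int, tuple[int, int]] = field(default_factory=dict)
    surface_points: list[int] = field(default_factory=list)
    normals: dict[int, NDArray[np.float64]] | None = None
    n_neighbors: int = 8

    def validate(self, k: int) -> None:
        for i, (a, b) in self.curve_neighbors.items():
            if not (0 <= i < k and 0 <= a < k and 0 <= b < k):
                raise ValueError(f"neighbor indices out of range for point {i}")
            if a == b:
                raise ValueError(f"curve neighbors of point {i} must be distinct")
        for i in self.surface_points:
            if not 0 <= i < k:
                raise ValueError(f"surface point index {i} out of range")
        overlap = set(self.curve_neighbors) & set(self.surface_points)
        if overlap:
            raise ValueError(f"points {sorted(overlap)} listed as both curve and surface")

    @property
    def sliding_indices(self) -> list[int]:
        return sorted(set(self.curve_neighbors) | set(self.surface_points))


@dataclass
class ProcrustesResult:
    """Output of :func:`gpa`: aligned unit-size shapes and their mean."""

    aligned: NDArray[np.float64]          # (n, k, 3)
    mean_shape: NDArray[np.float64]       # (k, 3), unit centroid size
    centroid_sizes: NDArray[np.float64]   # (n,)
    iterations: int
    converged: bool


# --------------------------------------------------------------------------
# Size and superimposition
# --------------------------------------------------------------------------

def centroid_size(config: LandmarkConfiguration | ArrayLike) -> float:
    """Square root of summed squared distances of points from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if pts.size == 0:
        raise ValueError("empty configuration")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _as_points(obj) -> NDArray[np.float64]:
    if isinstance(obj, LandmarkConfiguration):
        return np.asarray(obj.points, float)
    return np.asarray(obj, float)


def to_shape(points: ArrayLike) -> NDArray[np.float64]:
    """Center and scale to unit centroid size (the pre-shape of a configuration)."""
    pts = _as_points(points)
    centered = pts - pts.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return centered / size


def optimal_rotation(a: ArrayLike, b: ArrayLike) -> NDArray[np.float64]:
    """Rotation R (proper, det=+1) minimizing ||a @ R - b||_F for centered a, b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    flip = np.ones(a.shape[1])
    flip[-1] = d
    return u @ np.diag(flip) @ vt


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two shapes.

    Both inputs are reduced to pre-shapes (centered, unit centroid size);
    the distance is the root-sum-square coordinate difference after the
    optimal proper rotation.  Symmetric; zero iff the configurations agree
    up to translation, scale and rotation.
    """
    sa, sb = to_shape(_as_points(a)), to_shape(_as_points(b))
    if sa.shape != sb.shape:
        raise ValueError(f"shape mismatch: {sa.shape} vs {sb.shape}")
    r = optimal_rotation(sa, sb)
    return float(np.linalg.norm(sa @ r - sb))


def batched_procrustes_distance(
    a: NDArray[np.float64], b: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Partial Procrustes distances for stacks of configurations (m, k, 3).

    Vectorized over the leading axis; used by permutation machinery where
    thousands of pairwise mean-shape distances are needed.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a**2).sum(axis=(1, 2), keepdims=True))
    nb = np.sqrt((b**2).sum(axis=(1, 2), keepdims=True))
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("degenerate configuration in batch")
    a = a / na
    b = b / nb
    m = np.einsum("nki,nkj->nij", a, b)          # (m, 3, 3) cross-products
    u, s, vt = np.linalg.svd(m)
    det = np.linalg.det(u @ vt)
    s_signed = s.copy()
    s_signed[:, -1] *= np.sign(np.where(det == 0, 1.0, det))
    # ||aR - b||^2 = |a|^2 + |b|^2 - 2 tr(R' a' b) = 2 - 2 * sum(signed sv)
    d2 = np.clip(2.0 - 2.0 * s_signed.sum(axis=1), 0.0, None)
    return np.sqrt(d2)


def gpa(
    configs,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes analysis.

    Iteratively centers, scales each configuration to unit centroid size,
    rotates each to the current consensus by proper orthogonal least
    squares, and re-estimates the consensus (re-normalized to unit size),
    until the RMS change of the consensus falls below ``tol``.

    Returns a :class:`ProcrustesResult`; ``centroid_sizes`` holds the
    original (pre-scaling) sizes, the GM proxy for size.
    """
    pts = [np.asarray(_as_points(c), float) for c in configs]
    if len(pts) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = pts[0].shape[0]
    for i, p in enumerate(pts):
        if p.shape != (k, 3):
            raise ValueError(f"configuration {i} has shape {p.shape}, expected ({k}, 3)")
        if np.linalg.matrix_rank(p - p.mean(axis=0)) < 2:
            raise ValueError(f"configuration {i} is degenerate (rank < 2)")

    sizes = np.array([centroid_size(p) for p in pts])
    shapes = np.stack([to_shape(p) for p in pts])   # (n, k, 3)

    # initialize the consensus from the average pre-shape when well-defined
    # (then already-aligned input converges in one pass); fall back to the
    # first specimen if the raw average degenerates
    avg = shapes.mean(axis=0)
    if np.sqrt(np.sum((avg - avg.mean(axis=0)) ** 2)) > 0.1:
        mean = to_shape(avg)
    else:
        mean = shapes[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], mean)
        new_mean = to_shape(shapes.mean(axis=0))
        delta = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if delta < tol:
            converged = True
            break
    # final alignment to the converged mean
    for i in range(len(shapes)):
        shapes[i] = shapes[i] @ optimal_rotation(shapes[i], mean)
    return ProcrustesResult(
        aligned=shapes, mean_shape=mean, centroid_sizes=sizes,
        iterations=it, converged=converged,
    )


# --------------------------------------------------------------------------
# Thin-plate spline
# --------------------------------------------------------------------------

def _tps_kernel(r: NDArray[np.float64]) -> NDArray[np.float64]:
    # 3D biharmonic kernel, sign chosen so the bending form is PSD
    return -r


def _tps_system(reference: NDArray[np.float64]) -> NDArray[np.float64]:
    k = reference.shape[0]
    d = np.linalg.norm(reference[:, None, :] - reference[None, :, :], axis=-1)
    off = d[~np.eye(k, dtype=bool)]
    if off.size and off.min() < 1e-12:
        raise ValueError("coincident points make the TPS kernel singular")
    kk = _tps_kernel(d)
    q = np.hstack([np.ones((k, 1)), reference])           # (k, 4)
    top = np.hstack([kk, q])
    bot = np.hstack([q.T, np.zeros((4, 4))])
    return np.vstack([top, bot])


def tps_bending_energy_matrix(reference: ArrayLike) -> NDArray[np.float64]:
    """Bending-energy matrix B (k x k) of a 3D TPS anchored on ``reference``.

    For a displacement field with per-point values ``y`` (one coordinate at
    a time), the quadratic form ``y' B y`` is proportional to the integral
    of squared second derivatives of the interpolating spline (the factor
    is ``8*pi``); it vanishes exactly on affine fields.  B is symmetric
    positive semidefinite with a 4-dimensional affine null space.
    """
    ref = _as_points(reference)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference must be (k, 3)")
    k = ref.shape[0]
    if k < 5:
        raise ValueError("need at least 5 points for a nondegenerate 3D TPS")
    L = _tps_system(ref)
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (degenerate reference)") from exc
    b = Linv[:k, :k]
    return (b + b.T) / 2.0


def tps_bending_energy(reference: ArrayLike, values: ArrayLike) -> float:
    """Quadratic-form bending energy of per-point values/displacements.

    ``values`` may be (k,) for a scalar field or (k, d) for a displacement
    field (coordinates are penalized independently and summed).
    """
    b = tps_bending_energy_matrix(reference)
    v = np.asarray(values, float)
    if v.ndim == 1:
        v = v[:, None]
    return float(np.einsum("kd,kj,jd->", v, b, v))


def tps_warp(source: ArrayLike, target: ArrayLike, query_points: ArrayLike) -> NDArray[np.float64]:
    """TPS interpolant mapping ``source`` landmarks onto ``target``, applied to queries.

    Exact at the landmarks; reproduces affine maps exactly (the affine part
    lives in the null space of the bending penalty).
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape != tgt.shape:
        raise ValueError("source and target must have equal landmark counts")
    k = src.shape[0]
    L = _tps_system(src)
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    try:
        coef = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system") from exc
    w, a = coef[:k], coef[k:]
    q = np.asarray(query_points, float)
    squeeze = q.ndim == 1
    q = np.atleast_2d(q)
    d = np.linalg.norm(q[:, None, :] - src[None, :, :], axis=-1)
    out = _tps_kernel(d) @ w + a[0] + q @ a[1:]
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# Semilandmark sliding
# --------------------------------------------------------------------------

def _tangent_directions(
    points: NDArray[np.float64], scheme: SlidingScheme
) -> list[tuple[int, NDArray[np.float64]]]:
    """Per sliding point: (index, (m, 3) orthonormal tangent directions)."""
    out: list[tuple[int, NDArray[np.float64]]] = []
    for i, (a, b) in sorted(scheme.curve_neighbors.items()):
        chord = points[b] - points[a]
        n = np.linalg.norm(chord)
        if n < 1e-12:
            raise ValueError(f"coincident curve neighbors leave point {i} without a tangent")
        out.append((i, (chord / n)[None, :]))
    for i in sorted(scheme.surface_points):
        if scheme.normals is not None and i in scheme.normals:
            normal = np.asarray(scheme.normals[i], float)
            nn = np.linalg.norm(normal)
            if nn < 1e-12:
                raise ValueError(f"zero normal supplied for surface point {i}")
            normal = normal / nn
        else:
            # local PCA: the normal is the least-variance axis of the nearest neighbors
            d = np.linalg.norm(points - points[i], axis=1)
            nbr = np.argsort(d)[1 : scheme.n_neighbors + 1]
            local = points[nbr] - points[nbr].mean(axis=0)
            _, s, vt = np.linalg.svd(local, full_matrices=False)
            if s.size < 3 or s[1] < 1e-12:
                raise ValueError(f"degenerate neighborhood around surface point {i}")
            normal = vt[-1]
        # tangent plane = orthogonal complement of the normal
        basis = np.eye(3) - np.outer(normal, normal)
        u, s, _ = np.linalg.svd(basis)
        out.append((i, u[:, :2].T))
    return sorted(out, key=lambda t: t[0])


def slide_against_reference(
    shapes: NDArray[np.float64],
    scheme: SlidingScheme,
    reference: NDArray[np.float64],
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Slide each configuration's semilandmarks against a fixed reference.

    Each semilandmark moves along its tangent line (curve points) or within
    its tangent plane (surface points); the displacements jointly minimize
    the TPS bending energy of the deformation from ``reference`` to the
    configuration.  Fixed landmarks never move.

    Returns ``(slid, energy_before, energy_after)`` with per-specimen
    energies; by construction ``energy_after <= energy_before``.
    """
    shapes = np.asarray(shapes, float)
    single = shapes.ndim == 2
    if single:
        shapes = shapes[None]
    n, k, _ = shapes.shape
    scheme.validate(k)
    B = tps_bending_energy_matrix(reference)

    slid = shapes.copy()
    e_before = np.empty(n)
    e_after = np.empty(n)
    for s in range(n):
        y = shapes[s]
        e_before[s] = float(np.einsum("kd,kj,jd->", y, B, y))
        dirs = _tangent_directions(y, scheme)
        if not dirs:
            slid[s] = y
            e_after[s] = e_before[s]
            continue
        cols = []       # each: (k, 3) field moving one point along one direction
        for i, tangents in dirs:
            for t in tangents:
                col = np.zeros((k, 3))
                col[i] = t
                cols.append(col)
        U = np.stack(cols, axis=-1)                     # (k, 3, m)
        # minimize sum_d (y_d + U_d t)' B (y_d + U_d t)
        A = np.einsum("kdm,kj,jdp->mp", U, B, U)
        rhs = -np.einsum("kdm,kj,jd->m", U, B, y)
        t, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        ynew = y + np.einsum("kdm,m->kd", U, t)
        slid[s] = ynew
        e_after[s] = float(np.einsum("kd,kj,jd->", ynew, B, ynew))
    if single:
        return slid[0], e_before[0], e_after[0]
    return slid, e_before, e_after


def slide_semilandmarks(
    configs,
    scheme: SlidingScheme,
    reference: ArrayLike | None = None,
    max_outer_iter: int = 5,
    tol: float = 1e-8,
) -> tuple[NDArray[np.float64], ProcrustesResult]:
    """Iterative sliding: GPA -> slide against the consensus -> repeat.

    If ``reference`` is given, a single sliding pass against it is done
    first; otherwise the consensus of an initial GPA serves as reference.
    The outer loop stops when the consensus stabilizes (RMS change below
    ``tol``) or after ``max_outer_iter`` rounds — convergence is typically
    immediate.

    Returns the slid configurations (in Procrustes alignment) and the
    final :class:`ProcrustesResult`.
    """
    res = gpa(configs)
    shapes = res.aligned
    ref = to_shape(np.asarray(reference, float)) if reference is not None else res.mean_shape
    for _ in range(max_outer_iter):
        shapes, _, _ = slide_against_reference(shapes, scheme, ref)
        res = gpa(list(shapes))
        shapes = res.aligned
        delta = np.sqrt(np.mean((res.mean_shape - ref) ** 2))
        ref = res.mean_shape
        if delta < tol:
            break
    # sizes of the *input* configurations, not the re-normalized slid shapes
    res.centroid_sizes = np.array([centroid_size(c) for c in configs])
    return shapes, res
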
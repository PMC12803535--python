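"""Two-block partial least squares between bone-modeling maps and shape.

The map block (specimens x cells of %BR) and the shape block (specimens x
3k Procrustes coordinates) are column-centered and the cross-covariance
matrix is decomposed by SVD.  Each pair of singular vectors ("singular
warp" when one block is shape) captures a maximal-covariance axis;
specimens receive paired scores whose Pearson correlation summarizes the
covariation strength.  Significance of each pair's singular value is
assessed by permuting specimen rows of one block.

Blocks are not variance-standardized (covariance PLS), the convention for
shape-texture covariation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .bm import MeanMap, ResorptionMap


@dataclass
class PLSResult:
    """Singular value decomposition of the cross-covariance of two blocks."""

    singular_values: NDArray[np.float64]        # (r,) descending
    pct_total_covariance: NDArray[np.float64]   # 100 * s_i^2 / sum s^2
    left_vectors: NDArray[np.float64]           # (p, r)  map block
    right_vectors: NDArray[np.float64]          # (q, r)  shape block
    left_scores: NDArray[np.float64]            # (n, r)
    right_scores: NDArray[np.float64]           # (n, r)
    score_correlation: NDArray[np.float64]      # (r,)
    left_mean: NDArray[np.float64]
    right_mean: NDArray[np.float64]
    p_values: NDArray[np.float64] | None = None
    n_permutations: int | None = None
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return self.singular_values.size


def resolve_missing_cells(
    map_block: NDArray[np.float64], policy: str = "impute"
) -> tuple[NDArray[np.float64], NDArray[np.int_]]:
    """Resolve NaN cells in a specimens-x-cells %BR block before PLS.

    ``impute``: replace each missing value by that cell's cross-specimen
    mean.  ``drop``: remove every cell that is missing in any specimen.
    Returns the resolved block and the indices of the retained cells.
    """
    x = np.asarray(map_block, float).copy()
    nan = np.isnan(x)
    kept = np.arange(x.shape[1])
    if not nan.any():
        return x, kept
    if policy == "impute":
        cell_mean = np.nanmean(x, axis=0)
        if np.isnan(cell_mean).any():
            raise ValueError("some cells are missing in every specimen; drop them first")
        x[nan] = np.broadcast_to(cell_mean, x.shape)[nan]
        return x, kept
    if policy == "drop":
        kept = np.flatnonzero(~nan.any(axis=0))
        if kept.size == 0:
            raise ValueError("every cell is missing in at least one specimen")
        return x[:, kept], kept
    raise ValueError(f"unknown NA policy {policy!r}")


def _orient(u: NDArray, v: NDArray, scores_u: NDArray, scores_v: NDArray):
    """Fix sign per pair: shape-block vector non-negative on a reference axis.

    The reference axis is the first coordinate with a nonzero loading, so
    the orientation is deterministic and flip-consistent across blocks.
    """
    for j in range(v.shape[1]):
        col = v[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            v[:, j] *= -1
            u[:, j] *= -1
            scores_u[:, j] *= -1
            scores_v[:, j] *= -1
    return u, v, scores_u, scores_v


def two_block_pls(
    map_block, shape_block, na_policy: str = "impute"
) -> PLSResult:
    """Covariance PLS of a %BR map block against a Procrustes shape block.

    Both blocks are column-centered; the cross-covariance matrix
    ``X' Y / (n - 1)`` is decomposed by SVD.  Scores are the centered
    blocks projected on the singular vectors.  The number of pairs is
    ``min(p, q, n - 1)``.
    """
    x = np.asarray(map_block, float)
    y = np.asarray(shape_block, float)
    if y.ndim == 3:  # (n, k, 3) Procrustes stacks are accepted directly
        y = y.reshape(y.shape[0], -1)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("blocks must be 2D (specimens x variables)")
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must have equal specimen counts")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens")
    x, _ = resolve_missing_cells(x, na_policy)
    if np.isnan(y).any():
        raise ValueError("shape block contains NaN")
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - xm, y - ym
    if not xc.any():
        raise ValueError("map block is constant")
    if not yc.any():
        raise ValueError("shape block is constant")
    c = xc.T @ yc / (n - 1)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    r = min(s.size, n - 1)
    u, s, v = u[:, :r], s[:r], vt[:r].T
    scores_x = xc @ u
    scores_y = yc @ v
    u, v, scores_x, scores_y = _orient(u, v, scores_x, scores_y)
    with np.errstate(invalid="ignore"):
        corr = np.array(
            [
                np.corrcoef(scores_x[:, j], scores_y[:, j])[0, 1]
                if scores_x[:, j].std() > 0 and scores_y[:, j].std() > 0
                else np.nan
                for j in range(r)
            ]
        )
    total = np.sum(s**2)
    return PLSResult(
        singular_values=s,
        pct_total_covariance=100.0 * s**2 / total,
        left_vectors=u,
        right_vectors=v,
        left_scores=scores_x,
        right_scores=scores_y,
        score_correlation=corr,
        left_mean=xm,
        right_mean=ym,
    )


def pls_permutation_test(
    map_block,
    shape_block,
    n_iter: int = 1000,
    seed: int | None = None,
    na_policy: str = "impute",
) -> PLSResult:
    """Permutation p-values for each singular-value pair.

    Rows of the map block are permuted; each pair's observed singular
    value is compared with its own null distribution (the i-th singular
    value under permutation), with the add-one estimator.
    """
    res = two_block_pls(map_block, shape_block, na_policy)
    x = np.asarray(map_block, float)
    x, _ = resolve_missing_cells(x, na_policy)
    y = np.asarray(shape_block, float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    r = res.n_pairs
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, r))
    for it in range(n_iter):
        perm = rng.permutation(n)
        s = np.linalg.svd(xc[perm].T @ yc / (n - 1), compute_uv=False)
        null[it] = s[:r]
    ge = (null >= res.singular_values[None, :] - 1e-12).sum(axis=0)
    res.p_values = (1 + ge) / (1 + n_iter)
    res.n_permutations = n_iter
    res.seed = seed
    return res


def extreme_shape_and_map(
    result: PLSResult,
    pair_index: int,
    sd_multiplier: float,
    mean_shape,
    mean_map: ResorptionMap | MeanMap | NDArray[np.float64],
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.bool_]]:
    """Reconstruct the shape and map at ``sd_multiplier`` SDs along one pair.

    Each block's reconstruction is its mean plus the singular vector scaled
    by the multiplier times the SD of that pair's scores.  Map values are
    clipped to [0, 100]; the returned boolean mask flags clipped cells.
    """
    if not 0 <= pair_index < result.n_pairs:
        raise ValueError(f"pair index {pair_index} out of range")
    shape_mean = np.asarray(mean_shape, float)
    if isinstance(mean_map, (ResorptionMap, MeanMap)):
        map_mean = mean_map.values if isinstance(mean_map, ResorptionMap) else mean_map.mean_values
    else:
        map_mean = np.asarray(mean_map, float)
    sd_shape = result.right_scores[:, pair_index].std(ddof=1)
    sd_map = result.left_scores[:, pair_index].std(ddof=1)
    shape_ext = (
        shape_mean.ravel()
        + sd_multiplier * sd_shape * result.right_vectors[:, pair_index]
    ).reshape(shape_mean.shape)
    raw = map_mean + sd_multiplier * sd_map * result.left_vectors[:, pair_index]
    clipped_map = np.clip(raw, 0.0, 100.0)
    flags = ~np.isclose(raw, clipped_map)
    return shape_ext, clipped_map, flags
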
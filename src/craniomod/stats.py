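"""Growth/development quantification and inferential statistics.

*Growth* is change in size (centroid size) across age groups; *development*
is change in shape (Procrustes distance between age-group mean shapes).
Both are summarized as the four between-consecutive-age-group differences,
normalized to percentages of the total.

Inference: permutation tests on mean size and mean shape differences
between age groups (add-one Monte-Carlo p-values), and a one-way ANOVA
with Tukey HSD post hoc comparisons on region %BR.  For a single factor,
Type III and Type I sums of squares coincide, so the one-way ANOVA here is
the Type-III analysis appropriate for unequal group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import gm

INTERVAL_LABELS = ("AG1-AG2", "AG2-AG3", "AG3-AG4", "AG4-AG5")


@dataclass
class GrowthProfile:
    """Per-interval absolute and relative (percent-of-total) change."""

    region: str
    interval_labels: tuple[str, ...]
    absolute_differences: NDArray[np.float64]
    relative_percent: NDArray[np.float64]
    signed_differences: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.absolute_differences = np.asarray(self.absolute_differences, float)
        self.relative_percent = np.asarray(self.relative_percent, float)
        if abs(self.relative_percent.sum() - 100.0) > 1e-9:
            raise ValueError("relative percentages must sum to 100")


@dataclass
class PairwiseTestTable:
    """All unordered group pairs with a statistic and a p-value each."""

    pairs: list[tuple]
    statistics: NDArray[np.float64]
    p_values: NDArray[np.float64]
    n_iterations: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [a for a, _ in self.pairs],
                "group_b": [b for _, b in self.pairs],
                "statistic": self.statistics,
                "p_value": self.p_values,
            }
        )


# --------------------------------------------------------------------------
# Relative growth and development
# --------------------------------------------------------------------------

def relative_growth(mean_sizes_by_age_group, region: str = "") -> GrowthProfile:
    """Relative growth: consecutive mean-centroid-size differences as % of total."""
    means = np.asarray(mean_sizes_by_age_group, float)
    if means.shape != (5,):
        raise ValueError("need exactly 5 age-group mean sizes")
    signed = np.diff(means)
    absolute = np.abs(signed)
    total = absolute.sum()
    if total == 0:
        raise ValueError("no growth signal: all age-group means equal")
    return GrowthProfile(
        region=region,
        interval_labels=INTERVAL_LABELS,
        absolute_differences=absolute,
        relative_percent=100.0 * absolute / total,
        signed_differences=signed,
    )


def relative_development(mean_shapes_by_age_group, region: str = "") -> GrowthProfile:
    """Relative development: consecutive mean-shape Procrustes distances as % of total."""
    shapes = [np.asarray(s, float) for s in mean_shapes_by_age_group]
    if len(shapes) != 5:
        raise ValueError("need exactly 5 age-group mean shapes")
    absolute = np.array(
        [gm.procrustes_distance(shapes[i], shapes[i + 1]) for i in range(4)]
    )
    total = absolute.sum()
    if total < 1e-12:  # below rotation-solve round-off: identical shapes
        raise ValueError("no development signal: all age-group mean shapes identical")
    return GrowthProfile(
        region=region,
        interval_labels=INTERVAL_LABELS,
        absolute_differences=absolute,
        relative_percent=100.0 * absolute / total,
    )


# --------------------------------------------------------------------------
# Permutation tests
# --------------------------------------------------------------------------

def _addone_p(null_stats: NDArray[np.float64], observed: float) -> float:
    # (1 + b) / (1 + m): never returns 0, standard Monte-Carlo estimator
    return float((1 + np.sum(null_stats >= observed - 1e-12)) / (1 + null_stats.size))


def permutation_test_size(
    sizes_a, sizes_b, n_iter: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Permutation test on |mean(a) - mean(b)| of centroid sizes.

    Returns ``(statistic, p_value)`` with the add-one Monte-Carlo p.
    """
    a = np.asarray(sizes_a, float)
    b = np.asarray(sizes_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 specimens")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    rng = np.random.default_rng(seed)
    # vectorized: argsort of uniforms = independent random permutations
    order = np.argsort(rng.random((n_iter, n)), axis=1)
    perm = pooled[order]
    stat = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
    return observed, _addone_p(stat, observed)


def permutation_test_shape(
    shapes_a, shapes_b, n_iter: int = 1000, seed: int | None = None, aligned: bool = False
) -> tuple[float, float]:
    """Permutation test on the Procrustes distance between group mean shapes.

    The pooled sample is GPA-aligned once (unless ``aligned=True``), the
    statistic is the Procrustes distance between the two group mean shapes,
    and group labels are permuted over the aligned coordinates.
    """
    a = np.asarray(shapes_a, float)
    b = np.asarray(shapes_b, float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must be (n, k, 3) stacks with equal k")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 specimens")
    pooled = np.concatenate([a, b])
    if not aligned:
        res = gm.gpa(list(pooled))
        pooled = res.aligned
    n, na = pooled.shape[0], a.shape[0]
    observed = gm.procrustes_distance(pooled[:na].mean(axis=0), pooled[na:].mean(axis=0))

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_iter, n)), axis=1)
    flat = pooled.reshape(n, -1)
    means_a = flat[order[:, :na]].mean(axis=1).reshape(n_iter, *pooled.shape[1:])
    means_b = flat[order[:, na:]].mean(axis=1).reshape(n_iter, *pooled.shape[1:])
    stat = gm.batched_procrustes_distance(means_a, means_b)
    return float(observed), _addone_p(stat, observed)


def pairwise_permutation_tables(
    groups_sizes: dict[int, NDArray[np.float64]],
    groups_shapes: dict[int, NDArray[np.float64]],
    n_iter: int = 1000,
    seed: int | None = None,
) -> tuple[PairwiseTestTable, PairwiseTestTable]:
    """Size and shape permutation tests over all unordered age-group pairs."""
    keys = sorted(groups_sizes)
    if sorted(groups_shapes) != keys:
        raise ValueError("size and shape groups must cover the same age groups")
    ss = np.random.SeedSequence(seed)
    pairs, s_stat, s_p, d_stat, d_p = [], [], [], [], []
    for i, gi in enumerate(keys):
        for gj in keys[i + 1 :]:
            child = ss.spawn(1)[0]
            seeds = child.generate_state(2) % (2**31)
            st, p = permutation_test_size(
                groups_sizes[gi], groups_sizes[gj], n_iter, int(seeds[0])
            )
            dt, q = permutation_test_shape(
                groups_shapes[gi], groups_shapes[gj], n_iter, int(seeds[1])
            )
            pairs.append((gi, gj))
            s_stat.append(st)
            s_p.append(p)
            d_stat.append(dt)
            d_p.append(q)
    size_table = PairwiseTestTable(pairs, np.array(s_stat), np.array(s_p), n_iter, seed)
    shape_table = PairwiseTestTable(pairs, np.array(d_stat), np.array(d_p), n_iter, seed)
    return size_table, shape_table


# --------------------------------------------------------------------------
# ANOVA and Tukey HSD on region %BR
# --------------------------------------------------------------------------

def _split_groups(values, labels):
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = {}
    for lab in np.unique(labels):
        groups[lab] = values[labels == lab]
    if len(groups) < 2:
        raise ValueError("need at least 2 regions")
    for lab, v in groups.items():
        if v.size < 2:
            raise ValueError(f"region {lab!r} has fewer than 2 specimens")
    return groups


def anova_region_resorption(values, labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of %BR on facial region.

    With a single factor, Type III and sequential sums of squares coincide,
    so this is the unequal-n Type-III analysis.  Returns ``(F, p)``.
    """
    groups = _split_groups(values, labels)
    f, p = sps.f_oneway(*groups.values())
    return float(f), float(p)


def tukey_hsd(values, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD (Tukey-Kramer for unequal n) pairwise region comparisons.

    Returns a tidy frame with columns ``group_a, group_b, diff, lwr, upr,
    p_adjusted``; ``diff`` is mean(group_b) - mean(group_a) with groups in
    sorted label order, and each pair is labeled ``"b-a"``.
    """
    _split_groups(values, labels)  # validation
    res = pairwise_tukeyhsd(np.asarray(values, float), np.asarray(labels), alpha=alpha)
    frame = pd.DataFrame(
        data=res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    out = pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "pair": frame["group2"].astype(str) + "-" + frame["group1"].astype(str),
            "diff": res.meandiffs,
            "lwr": res.confint[:, 0],
            "upr": res.confint[:, 1],
            "p_adjusted": res.pvalues,
        }
    )
    # zero residual variance: the studentized range is 0/0 for tied means
    # (p = 1) and effectively infinite for distinct means (p = 0)
    nan_p = out["p_adjusted"].isna()
    out.loc[nan_p & (out["diff"] == 0), "p_adjusted"] = 1.0
    out.loc[nan_p & (out["diff"] != 0), "p_adjusted"] = 0.0
    return out


def region_resorption_summary(values, labels, age_groups) -> pd.DataFrame:
    """Per-region %BR summary: per-age-group medians plus pooled mean (SD)."""
    df = pd.DataFrame(
        {"region": labels, "age_group": age_groups, "pct_br": np.asarray(values, float)}
    )
    med = (
        df.pivot_table(index="region", columns="age_group", values="pct_br", aggfunc="median")
        .rename(columns=lambda g: f"AG{g}_median")
    )
    pooled = df.groupby("region")["pct_br"].agg(pooled_mean="mean", pooled_sd="std")
    return med.join(pooled).reset_index()
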
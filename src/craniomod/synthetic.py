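"""Synthetic skeletal cohorts with known ontogenetic structure.

Generates landmark configurations and bone-modeling grids for five
dental-development age groups (AG 1-5) with a planted ground truth:

* per-age-group mean centroid sizes follow a cumulative growth profile;
* mean shapes are displaced along one fixed trajectory in shape space,
  with per-interval step magnitudes given by a development profile;
* per-cell %BR maps are a smooth regional baseline plus a rank-1 coupling
  between a specimen's shape score and a planted map pattern, plus noise,
  clipped to [0, 100].

Because every generating parameter is recorded in ``SyntheticCohort.truth``,
downstream estimates (relative growth/development, PLS singular vectors)
can be checked against what was planted.  The cohorts make no claim of
anatomical realism: shapes are random point clouds, not faces, and grids
are index-ordered, not anatomically placed.

Default cohort sizes and regional %BR levels emulate the structure of an
osteological study of facial ontogeny: 35-51 individuals spread unevenly
over five age groups, five facial regions with mean %BR between roughly
11 and 35 and between-specimen SD around 8-17 percentage points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .bm import REGIONS, BoneModelingGrid, GridCell
from .gm import LandmarkConfiguration, centroid_size, to_shape

# Pooled-AG mean %BR levels by region, on the scale reported for human
# facial bone: the maxilla is by far the most resorptive.
REGION_BASELINE_LEVELS: dict[str, float] = {
    "brow_ridge": 15.0,
    "zygomatic": 17.0,
    "maxilla": 35.0,
    "mandible_external": 11.0,
    "mandible_internal": 12.0,
}

# Age-group sizes patterned on a real osteological series: few neonates
# and old adults, most specimens in the deciduous-dentition stage.
DEFAULT_N_PER_AGE_GROUP = (5, 15, 13, 5, 8)


class CohortSpecError(ValueError):
    """A CohortSpec field failed validation; the message names the field."""


@dataclass
class CohortSpec:
    """Generating parameters of one single-region synthetic cohort.

    Parameters
    ----------
    n_per_age_group : 5 ints
        Specimens per age group AG 1-5.
    n_landmarks, n_semilandmarks : int
        Fixed landmarks and (curve) semilandmarks per configuration.
    n_cells : int
        Grid cells per region (5 mm cells).
    base_size : float
        Mean centroid size (mm) of AG 1.
    growth_profile : 4 floats
        Increments of mean centroid size between consecutive age groups.
    development_profile : 4 floats
        Magnitudes of mean-shape displacement between consecutive age
        groups (Procrustes-like units along the planted trajectory).
    covariation_strength : float in [0, 1]
        Coupling of the specimen shape score into the map block.
    noise_sd_shape : float
        Isotropic landmark noise SD (mm).
    noise_sd_map : float
        Cellwise map noise SD (percentage points).
    between_specimen_sd_map : float
        SD of a per-specimen map level offset (percentage points); drives
        the between-specimen spread of region %BR.
    map_signal_scale : float
        Percentage points of map signal per unit shape score at
        ``covariation_strength = 1``.
    missing_rate : float in [0, 1)
        Expected fraction of grid cells flagged missing.
    """

    n_per_age_group: tuple[int, ...] = DEFAULT_N_PER_AGE_GROUP
    n_landmarks: int = 10
    n_semilandmarks: int = 20
    n_cells: int = 60
    region: str = "maxilla"
    base_size: float = 120.0
    growth_profile: tuple[float, ...] = (30.0, 15.0, 10.0, 5.0)
    development_profile: tuple[float, ...] = (0.06, 0.03, 0.02, 0.01)
    covariation_strength: float = 0.6
    noise_sd_shape: float = 1.0
    noise_sd_map: float = 5.0
    between_specimen_sd_map: float = 10.0
    map_signal_scale: float = 150.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_age_group = tuple(int(n) for n in self.n_per_age_group)
        self.growth_profile = tuple(float(g) for g in self.growth_profile)
        self.development_profile = tuple(float(d) for d in self.development_profile)
        if len(self.n_per_age_group) != 5 or any(n < 1 for n in self.n_per_age_group):
            raise CohortSpecError("n_per_age_group must be 5 counts, each >= 1")
        for name in ("n_landmarks", "n_semilandmarks", "n_cells"):
            if getattr(self, name) < 1:
                raise CohortSpecError(f"{name} must be >= 1")
        if self.n_landmarks + self.n_semilandmarks < 5:
            raise CohortSpecError("n_landmarks + n_semilandmarks must be >= 5")
        if len(self.growth_profile) != 4 or any(g < 0 for g in self.growth_profile):
            raise CohortSpecError("growth_profile must be 4 non-negative increments")
        if len(self.development_profile) != 4 or any(d < 0 for d in self.development_profile):
            raise CohortSpecError("development_profile must be 4 non-negative magnitudes")
        if not 0 <= self.covariation_strength <= 1:
            raise CohortSpecError("covariation_strength must lie in [0, 1]")
        for name in ("noise_sd_shape", "noise_sd_map", "between_specimen_sd_map",
                     "map_signal_scale", "base_size"):
            if getattr(self, name) < 0:
                raise CohortSpecError(f"{name} must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise CohortSpecError("missing_rate must lie in [0, 1)")
        if self.region not in REGIONS:
            raise CohortSpecError(f"region must be one of {REGIONS}")

    @property
    def k(self) -> int:
        return self.n_landmarks + self.n_semilandmarks

    @property
    def n_specimens(self) -> int:
        return sum(self.n_per_age_group)

    @property
    def target_mean_sizes(self) -> NDArray[np.float64]:
        return self.base_size + np.concatenate([[0.0], np.cumsum(self.growth_profile)])


@dataclass
class Specimen:
    specimen_id: str
    age_group: int
    landmarks: LandmarkConfiguration
    grid: BoneModelingGrid


@dataclass
class SyntheticCohort:
    """One region's generated specimens plus the generating ground truth."""

    spec: CohortSpec
    specimens: list[Specimen]
    truth: dict = field(default_factory=dict)

    @property
    def age_groups(self) -> NDArray[np.int_]:
        return np.array([s.age_group for s in self.specimens])


def _smooth_pattern(n_cells: int, coeffs: NDArray[np.float64]) -> NDArray[np.float64]:
    """Low-order polynomial over normalized cell index, zero mean, unit norm."""
    t = np.linspace(-1.0, 1.0, n_cells)
    v = np.polynomial.polynomial.polyval(t, coeffs)
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        v = t - t.mean()
        nrm = np.linalg.norm(v)
    return v / nrm


def _grid_from_values(region: str, values: NDArray[np.float64]) -> BoneModelingGrid:
    """Translate per-cell %BR values into coded grid cells (5 mm side)."""
    cells = []
    for i, v in enumerate(values):
        if v <= 0.0:
            cells.append(GridCell(cell_id=i, status="formation_only"))
        elif v >= 100.0:
            cells.append(GridCell(cell_id=i, status="resorption_only"))
        else:
            cells.append(
                GridCell(cell_id=i, status="mixed", resorptive_area=v / 100.0 * 25.0)
            )
    return BoneModelingGrid(region=region, cells=cells, total_region_area=25.0 * len(values))


def generate_cohort(spec: CohortSpec, baseline_level: float | None = None) -> SyntheticCohort:
    """Generate one single-region cohort from a :class:`CohortSpec`.

    Deterministic given ``spec.seed``.  ``baseline_level`` overrides the
    region's default mean %BR level.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k

    # base mean shape (unit centroid size) and a fixed shape-space trajectory
    base = to_shape(rng.normal(size=(k, 3)))
    traj = rng.normal(size=(k, 3))
    traj -= traj.mean(axis=0)
    traj -= np.sum(traj * base) * base          # orthogonal to base: pure shape change
    traj /= np.linalg.norm(traj)

    cum_dev = np.concatenate([[0.0], np.cumsum(spec.development_profile)])
    mean_shapes = [to_shape(base + c * traj) for c in cum_dev]
    target_sizes = spec.target_mean_sizes

    # planted map structure
    level = REGION_BASELINE_LEVELS.get(spec.region, 20.0) if baseline_level is None else baseline_level
    # smooth cellwise baseline, ~5 pp per-cell amplitude around the regional level
    # (_smooth_pattern is unit-norm, so scale by sqrt(n_cells) for O(1) entries)
    baseline_pattern = _smooth_pattern(spec.n_cells, rng.normal(size=4))
    baseline = level + 5.0 * np.sqrt(spec.n_cells) * baseline_pattern

    w_map = _smooth_pattern(spec.n_cells, rng.normal(size=5))

    roles = ["fixed"] * spec.n_landmarks + ["curve_semilandmark"] * spec.n_semilandmarks
    labels = [f"lm{i}" for i in range(spec.n_landmarks)] + [
        f"slm{i}" for i in range(spec.n_semilandmarks)
    ]

    specimens: list[Specimen] = []
    scores = []
    idx = 0
    for g, n_g in enumerate(spec.n_per_age_group, start=1):
        m_g = mean_shapes[g - 1]
        for _ in range(n_g):
            pts = target_sizes[g - 1] * m_g + rng.normal(
                scale=spec.noise_sd_shape, size=(k, 3)
            )
            # shape score: projection of the specimen's pre-shape onto the trajectory
            s_i = float(np.sum((to_shape(pts) - base) * traj))
            scores.append(s_i)
            signal = spec.covariation_strength * spec.map_signal_scale * s_i
            offset = rng.normal(scale=spec.between_specimen_sd_map)
            values = (
                baseline
                + signal * w_map * np.sqrt(spec.n_cells)
                + offset
                + rng.normal(scale=spec.noise_sd_map, size=spec.n_cells)
            )
            values = np.clip(values, 0.0, 100.0)
            grid = _grid_from_values(spec.region, values)
            if spec.missing_rate > 0:
                grid = apply_missingness(
                    grid, spec.missing_rate, seed=int(rng.integers(2**31))
                )
            config = LandmarkConfiguration(
                specimen_id=f"{spec.region}_{idx:03d}",
                region=spec.region,
                points=pts,
                labels=list(labels),
                roles=list(roles),
            )
            specimens.append(
                Specimen(
                    specimen_id=config.specimen_id,
                    age_group=g,
                    landmarks=config,
                    grid=grid,
                )
            )
            idx += 1

    truth = {
        "base_shape": base,
        "trajectory": traj,
        "mean_shapes": mean_shapes,
        "target_mean_sizes": target_sizes,
        "baseline": baseline,
        "map_vector": w_map,
        "shape_scores": np.array(scores),
        "map_gain": spec.covariation_strength * spec.map_signal_scale * np.sqrt(spec.n_cells),
        "seed": spec.seed,
    }
    return SyntheticCohort(spec=spec, specimens=specimens, truth=truth)


def apply_missingness(grid: BoneModelingGrid, rate: float, seed: int) -> BoneModelingGrid:
    """Flag an expected fraction ``rate`` of cells as missing (new grid).

    Each cell is flagged independently with probability ``rate``;
    reproducible given ``seed``.  Cells not flagged are untouched.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return grid
    rng = np.random.default_rng(seed)
    mask = rng.random(grid.n_cells) < rate
    cells = []
    for cell, m in zip(grid.cells, mask):
        if m:
            cells.append(GridCell(cell_id=cell.cell_id, side_length=cell.side_length,
                                  status="missing"))
        else:
            cells.append(cell)
    return BoneModelingGrid(
        region=grid.region, cells=cells, total_region_area=grid.total_region_area
    )


def generate_study(
    base_spec: CohortSpec | None = None,
    regions: tuple[str, ...] = REGIONS,
    seed: int = 0,
) -> dict[str, SyntheticCohort]:
    """Generate one cohort per facial region with region-specific %BR levels.

    Region seeds are derived from ``seed`` with :class:`numpy.random.SeedSequence`
    so the study is reproducible as a whole and per region.
    """
    if base_spec is None:
        base_spec = CohortSpec(seed=seed)
    children = np.random.SeedSequence(seed).spawn(len(regions))
    out = {}
    for region, child in zip(regions, children):
        spec = dataclasses.replace(
            base_spec, region=region, seed=int(child.generate_state(1)[0] % (2**31))
        )
        out[region] = generate_cohort(spec)
    return out
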
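"""Percent-bone-resorption (%BR) quantification on gridded bone surfaces.

A replica of the periosteal surface is divided into 5 x 5 mm grid cells;
each cell is scored for osteoclastic resorption (Howship's lacunae) versus
osteoblastic formation.  Cells showing only formation are coded 0 %BR,
cells showing only resorption 100 %BR; mixed cells are measured (optionally
on a refined 2.5 mm subgrid) as resorptive area over cell area.  Cells with
missing surface are excluded; a cell that is partly missing but otherwise
shows a single activity is promoted to that activity (neighboring areas
tend to share cellular activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

REGIONS = (
    "brow_ridge",
    "zygomatic",
    "maxilla",
    "mandible_external",
    "mandible_internal",
)

STATUSES = (
    "formation_only",
    "resorption_only",
    "mixed",
    "missing",
    "partial_missing_with_formation",
    "partial_missing_with_resorption",
)

_MISSING = float("nan")


@dataclass
class GridCell:
    """One grid square on a surface replica.

    ``resorptive_area`` is the measured resorptive surface within the cell
    (mm^2); it is only required for ``mixed`` cells — for the pure statuses
    it is implied by the coding rules and checked for consistency when set.
    """

    cell_id: int
    side_length: float = 5.0
    resorptive_area: float | None = None
    status: str = "mixed"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown cell status {self.status!r}")
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.resorptive_area is not None:
            if not 0 <= self.resorptive_area <= self.area + 1e-9:
                raise ValueError(
                    f"cell {self.cell_id}: resorptive_area {self.resorptive_area} "
                    f"outside [0, {self.area}]"
                )

    @property
    def area(self) -> float:
        return self.side_length**2


@dataclass
class BoneModelingGrid:
    """All grid cells of one specimen-region, in stable anatomical order.

    Cell ordering is the cross-specimen correspondence: grids of the same
    region must index cells identically.  ``total_region_area`` is the
    independently measured surface area of the region (mm^2), kept for
    reporting; region %BR is computed from the cell areas.
    """

    region: str
    cells: list[GridCell] = field(default_factory=list)
    total_region_area: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class ResorptionMap:
    """Per-cell %BR values for one specimen-region; NaN marks missing cells."""

    region: str
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < -1e-9 or present.max() > 100 + 1e-9):
            raise ValueError("%BR values must lie in [0, 100]")


@dataclass
class MeanMap:
    """Cellwise mean %BR over the specimens of one age group."""

    region: str
    age_group: int
    mean_values: NDArray[np.float64]
    n_contributing: NDArray[np.int_]

    def __post_init__(self) -> None:
        self.mean_values = np.asarray(self.mean_values, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if not np.array_equal(np.isnan(self.mean_values), self.n_contributing == 0):
            raise ValueError("mean_values must be missing exactly where n_contributing is 0")


# --------------------------------------------------------------------------
# Cell-level quantification
# --------------------------------------------------------------------------

def cell_percent_resorption(resorptive_area: float, cell_area: float) -> float:
    """%BR of one cell: 100 x resorptive area / cell area."""
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    if not 0 <= resorptive_area <= cell_area + 1e-9:
        raise ValueError(
            f"resorptive_area {resorptive_area} outside [0, {cell_area}]"
        )
    return 100.0 * resorptive_area / cell_area


def code_cell(cell: GridCell) -> float:
    """Code one cell to a %BR value (NaN if the cell surface is missing).

    Formation-only cells are 0, resorption-only cells are 100.  A partly
    missing cell whose preserved surface shows a single activity is treated
    as fully showing that activity.  Mixed cells use the measured
    resorptive area.
    """
    s = cell.status
    if s == "missing":
        return _MISSING
    if s in ("formation_only", "partial_missing_with_formation"):
        if cell.resorptive_area not in (None, 0.0):
            raise ValueError(
                f"cell {cell.cell_id}: status {s} but resorptive_area "
                f"{cell.resorptive_area} != 0"
            )
        return 0.0
    if s in ("resorption_only", "partial_missing_with_resorption"):
        if cell.resorptive_area is not None and not math.isclose(
            cell.resorptive_area, cell.area, rel_tol=1e-9
        ):
            raise ValueError(
                f"cell {cell.cell_id}: status {s} but resorptive_area "
                f"{cell.resorptive_area} != cell area {cell.area}"
            )
        return 100.0
    # mixed
    if cell.resorptive_area is None:
        raise ValueError(f"cell {cell.cell_id}: mixed cell without measured resorptive_area")
    return cell_percent_resorption(cell.resorptive_area, cell.area)


def coded_resorptive_area(cell: GridCell) -> float:
    """Resorptive area (mm^2) implied by the coding rules; NaN if missing."""
    v = code_cell(cell)
    return v / 100.0 * cell.area if not math.isnan(v) else _MISSING


def subdivide_mixed_cell(cell: GridCell, sub_areas, tol: float = 1e-6) -> list[GridCell]:
    """Refine a mixed 5 mm cell into four 2.5 mm subcells.

    ``sub_areas`` gives the four measured resorptive areas (mm^2, each in
    [0, 6.25]).  When the parent's resorptive area was measured, the
    subdivision must conserve it within ``tol``.  Subcells are classified
    by the same coding rules (0 -> formation_only, full -> resorption_only,
    else mixed).
    """
    if cell.status != "mixed":
        raise ValueError("only mixed cells are subdivided")
    if cell.side_length != 5.0:
        raise ValueError("subdivision applies to 5 mm cells")
    sub_areas = [float(a) for a in sub_areas]
    if len(sub_areas) != 4:
        raise ValueError("need exactly 4 sub-areas")
    sub_side = cell.side_length / 2.0
    sub_cell_area = sub_side**2
    for a in sub_areas:
        if not 0 <= a <= sub_cell_area + 1e-9:
            raise ValueError(f"sub-area {a} outside [0, {sub_cell_area}]")
    if cell.resorptive_area is not None:
        if abs(sum(sub_areas) - cell.resorptive_area) > tol:
            raise ValueError(
                f"sub-areas sum to {sum(sub_areas)}, parent measured "
                f"{cell.resorptive_area}"
            )
    out = []
    for j, a in enumerate(sub_areas):
        if a == 0:
            status, area = "formation_only", None
        elif math.isclose(a, sub_cell_area, rel_tol=1e-9):
            status, area = "resorption_only", None
        else:
            status, area = "mixed", a
        out.append(
            GridCell(
                cell_id=cell.cell_id * 4 + j,
                side_length=sub_side,
                resorptive_area=area,
                status=status,
            )
        )
    return out


# --------------------------------------------------------------------------
# Region- and cohort-level quantification
# --------------------------------------------------------------------------

def resorption_map(grid: BoneModelingGrid) -> ResorptionMap:
    """Code every cell of a grid into a per-cell %BR map."""
    return ResorptionMap(
        region=grid.region,
        values=np.array([code_cell(c) for c in grid.cells], dtype=float),
    )


def region_percent_resorption(grid: BoneModelingGrid) -> float:
    """Total %BR of a region: summed resorptive areas over summed cell areas.

    Missing cells are excluded from both numerator and denominator, so a
    poorly preserved specimen is not biased toward low resorption.
    """
    num = 0.0
    den = 0.0
    for cell in grid.cells:
        a = coded_resorptive_area(cell)
        if math.isnan(a):
            continue
        num += a
        den += cell.area
    if den == 0:
        raise ValueError(f"all cells missing in region {grid.region}")
    return 100.0 * num / den


def mean_map(maps: list[ResorptionMap], age_group: int) -> MeanMap:
    """Cellwise mean %BR across specimens of one age group.

    Missing cells are excluded cell by cell; a mean cell is missing only
    when no specimen contributes to it.
    """
    if not maps:
        raise ValueError("no maps given")
    region = maps[0].region
    n_cells = maps[0].values.size
    for m in maps:
        if m.region != region:
            raise ValueError(f"region mismatch: {m.region} vs {region}")
        if m.values.size != n_cells:
            raise ValueError(
                f"cell count mismatch: {m.values.size} vs {n_cells}"
            )
    stack = np.stack([m.values for m in maps])
    present = ~np.isnan(stack)
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, np.nansum(np.where(present, stack, 0.0), axis=0) / np.maximum(n, 1), np.nan)
    return MeanMap(region=region, age_group=age_group, mean_values=means, n_contributing=n)


# --------------------------------------------------------------------------
# Mesh projection
# --------------------------------------------------------------------------

def project_map_to_mesh(
    rmap: ResorptionMap | MeanMap,
    n_vertices: int,
    cell_assignment: NDArray[np.int_],
) -> tuple[NDArray[np.float64], NDArray[np.bool_]]:
    """Paint per-cell %BR values onto mesh vertices.

    ``cell_assignment`` maps each vertex to a cell index, or -1 for
    vertices outside the gridded area.  Returns ``(vertex_values, flagged)``
    where ``flagged`` marks vertices that are unmapped or map to a missing
    cell; their values are NaN and they are excluded from any color range.
    """
    values = rmap.values if isinstance(rmap, ResorptionMap) else rmap.mean_values
    assignment = np.asarray(cell_assignment, dtype=int)
    if assignment.shape != (n_vertices,):
        raise ValueError(f"cell_assignment must have length {n_vertices}")
    valid = assignment >= 0
    if valid.any() and assignment[valid].max() >= values.size:
        raise ValueError("cell_assignment references a nonexistent cell")
    out = np.full(n_vertices, np.nan)
    out[valid] = values[assignment[valid]]
    flagged = ~valid | np.isnan(out)
    return out, flagged
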
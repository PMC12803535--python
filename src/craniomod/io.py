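"""File formats: TPS and CSV landmark files, grid CSV, map JSON, manifests,
and colored-PLY mesh export of %BR maps.

The TPS dialect supported is the common morphometrics one: ``LM3=k``
followed by k whitespace-separated coordinate rows, then an ``ID=`` line;
``SCALE=`` lines are accepted and ignored.  Readers and writers are
mutually inverse on valid data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bm import BoneModelingGrid, GridCell, MeanMap, ResorptionMap
from .gm import LandmarkConfiguration

GRID_COLUMNS = [
    "specimen_id",
    "region",
    "cell_id",
    "side_length_mm",
    "resorptive_area_mm2",
    "status",
]


# --------------------------------------------------------------------------
# Landmarks: TPS dialect
# --------------------------------------------------------------------------

def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    lines = []
    for c in configs:
        lines.append(f"LM3={c.k}")
        for p in c.points:
            lines.append(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
        lines.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path, region: str = "") -> list[LandmarkConfiguration]:
    """Parse a TPS file into configurations; errors carry line numbers."""
    out: list[LandmarkConfiguration] = []
    points: list[list[float]] = []
    expected = None
    spec_id = None
    seen: set[str] = set()
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal points, expected, spec_id
        if expected is None:
            return
        if len(points) != expected:
            raise ValueError(
                f"{path}:{lineno}: specimen {spec_id or '<unnamed>'} has "
                f"{len(points)} points, header says {expected}"
            )
        sid = spec_id if spec_id is not None else f"specimen_{len(out)}"
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate specimen id {sid!r}")
        seen.add(sid)
        out.append(
            LandmarkConfiguration(specimen_id=sid, region=region, points=np.array(points))
        )
        points, expected, spec_id = [], None, None

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            flush(lineno)
            try:
                expected = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed count line {line!r}") from exc
            start_line = lineno
        elif upper.startswith("ID="):
            spec_id = line.split("=", 1)[1].strip()
            flush(lineno)
        elif upper.startswith("SCALE=") or upper.startswith("IMAGE="):
            continue
        else:
            if expected is None:
                raise ValueError(f"{path}:{lineno}: coordinate row outside an LM3 block")
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                points.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
    flush(start_line + (expected or 0) + 1 if expected is not None else 0)
    return out


# --------------------------------------------------------------------------
# Landmarks: long-format CSV
# --------------------------------------------------------------------------

def write_landmarks_csv(configs: list[LandmarkConfiguration], path) -> None:
    rows = []
    for c in configs:
        for lab, role, p in zip(c.labels, c.roles, c.points):
            rows.append(
                {
                    "specimen_id": c.specimen_id,
                    "region": c.region,
                    "label": lab,
                    "role": role,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                }
            )
    # %.17g round-trips float64 exactly through read_csv
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_landmarks_csv(path) -> list[LandmarkConfiguration]:
    # round_trip parsing: the default fast parser is not correctly rounded
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen_id", "label", "role", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    ids = list(dict.fromkeys(df["specimen_id"]))  # preserve file order
    for sid in ids:
        sub = df[df["specimen_id"] == sid]
        out.append(
            LandmarkConfiguration(
                specimen_id=str(sid),
                region=str(sub["region"].iloc[0]) if "region" in sub else "",
                points=sub[["x", "y", "z"]].to_numpy(float),
                labels=[str(v) for v in sub["label"]],
                roles=[str(v) for v in sub["role"]],
            )
        )
    return out


# --------------------------------------------------------------------------
# Grids and maps
# --------------------------------------------------------------------------

def grids_to_frame(grids: dict[str, BoneModelingGrid]) -> pd.DataFrame:
    rows = []
    for sid, grid in grids.items():
        for cell in grid.cells:
            rows.append(
                {
                    "specimen_id": sid,
                    "region": grid.region,
                    "cell_id": cell.cell_id,
                    "side_length_mm": cell.side_length,
                    "resorptive_area_mm2": cell.resorptive_area,
                    "status": cell.status,
                }
            )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def write_grids_csv(grids: dict[str, BoneModelingGrid], path) -> None:
    grids_to_frame(grids).to_csv(path, index=False, float_format="%.17g")


def read_grids_csv(path) -> dict[str, BoneModelingGrid]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(GRID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, BoneModelingGrid] = {}
    for sid, sub in df.groupby("specimen_id", sort=False):
        cells = []
        for _, row in sub.sort_values("cell_id").iterrows():
            area = row["resorptive_area_mm2"]
            cells.append(
                GridCell(
                    cell_id=int(row["cell_id"]),
                    side_length=float(row["side_length_mm"]),
                    resorptive_area=None if pd.isna(area) else float(area),
                    status=str(row["status"]),
                )
            )
        out[str(sid)] = BoneModelingGrid(region=str(sub["region"].iloc[0]), cells=cells)
    return out


def write_map_json(m: ResorptionMap | MeanMap, path) -> None:
    if isinstance(m, MeanMap):
        payload = {
            "region": m.region,
            "age_group": int(m.age_group),
            "values": [None if np.isnan(v) else float(v) for v in m.mean_values],
            "n_contributing": [int(n) for n in m.n_contributing],
        }
    else:
        payload = {
            "region": m.region,
            "values": [None if np.isnan(v) else float(v) for v in m.values],
        }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_map_json(path) -> ResorptionMap | MeanMap:
    payload = json.loads(Path(path).read_text())
    values = np.array(
        [np.nan if v is None else float(v) for v in payload["values"]], dtype=float
    )
    if "age_group" in payload:
        return MeanMap(
            region=payload["region"],
            age_group=int(payload["age_group"]),
            mean_values=values,
            n_contributing=np.asarray(payload["n_contributing"], int),
        )
    return ResorptionMap(region=payload["region"], values=values)


# --------------------------------------------------------------------------
# Mesh rendering
# --------------------------------------------------------------------------

def grid_surface_mesh(n_cells: int, cols: int = 10, verts_per_cell_side: int = 2):
    """Planar triangulated stand-in surface with a vertex-to-cell assignment.

    Builds a rows x cols arrangement of 5 mm quads (one per grid cell, row-
    major like the cell index) and returns ``(vertices, faces, assignment)``.
    A synthetic stand-in for a real bone surface mesh: geometry is flat.
    """
    import trimesh

    cols = min(cols, n_cells)
    rows = (n_cells + cols - 1) // cols
    side = 5.0
    nv = verts_per_cell_side
    xs = np.linspace(0, cols * side, cols * nv)
    ys = np.linspace(0, rows * side, rows * nv)
    xx, yy = np.meshgrid(xs, ys)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    faces = []
    w = cols * nv
    for j in range(rows * nv - 1):
        for i in range(w - 1):
            a = j * w + i
            faces.append([a, a + 1, a + w])
            faces.append([a + 1, a + w + 1, a + w])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    cell_col = np.clip((vertices[:, 0] // side).astype(int), 0, cols - 1)
    cell_row = np.clip((vertices[:, 1] // side).astype(int), 0, rows - 1)
    assignment = cell_row * cols + cell_col
    assignment[assignment >= n_cells] = -1
    return mesh, assignment


def write_colored_ply(mesh, vertex_values, flagged, path, vmin=0.0, vmax=100.0) -> None:
    """Export a mesh with %BR painted as vertex colors (ASCII PLY).

    Cold tones mark high %BR (resorption), warm tones low %BR (formation);
    flagged vertices are neutral gray.
    """
    import matplotlib

    cmap = matplotlib.colormaps["coolwarm_r"]
    vals = np.asarray(vertex_values, float)
    norm = np.clip((vals - vmin) / max(vmax - vmin, 1e-12), 0, 1)
    colors = np.zeros((len(vals), 4), dtype=np.uint8)
    ok = ~np.asarray(flagged, bool)
    colors[ok] = (np.asarray(cmap(norm[ok])) * 255).astype(np.uint8)
    colors[~ok] = (128, 128, 128, 255)
    mesh = mesh.copy()
    mesh.visual.vertex_colors = colors
    Path(path).write_bytes(mesh.export(file_type="ply", encoding="ascii"))


# --------------------------------------------------------------------------
# Manifest and config hashing
# --------------------------------------------------------------------------

def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_manifest(path, *, specimens, seed, truth_summary=None, extra=None) -> None:
    payload = {
        "specimens": specimens,
        "seed": seed,
        "truth": truth_summary,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")
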
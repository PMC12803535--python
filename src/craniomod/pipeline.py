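"""End-to-end workflow: simulate -> quantify -> align -> stats -> PLS -> render.

Each stage is a thin orchestration over the library modules and writes tidy
CSV/JSON tables into an output directory.  Every output carries the config
hash and master seed, and all stage seeds are spawned from the master seed,
so a rerun with the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bm, gm, io, pls, stats
from .synthetic import CohortSpec, SyntheticCohort, generate_study

log = logging.getLogger("craniomod")


@dataclass
class AnalysisConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    out_dir: str = "results"
    regions: tuple[str, ...] = bm.REGIONS
    seed: int = 0
    n_permutations: int = 1000
    na_policy: str = "impute"
    gpa_tol: float = 1e-8
    sliding_outer_iter: int = 5
    render_meshes: bool = False
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: permutation stages are stochastic")
        if self.na_policy not in ("impute", "drop"):
            raise ValueError("na_policy must be 'impute' or 'drop'")
        self.regions = tuple(self.regions)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def hash(self) -> str:
        # identifies the analysis, not the destination: output location and
        # rendering toggles do not change any computed number
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("render_meshes")
        return io.config_hash(payload)


def _stamp(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.hash()
    df["seed"] = config.seed
    return df


def _write(df: pd.DataFrame, path: Path, config: AnalysisConfig) -> None:
    _stamp(df, config).to_csv(path, index=False, float_format="%.10g")


def default_sliding_scheme(spec: CohortSpec) -> gm.SlidingScheme:
    """Chain the generated curve semilandmarks between their index neighbors."""
    k = spec.k
    neighbors = {}
    for i in range(spec.n_landmarks, k):
        a = i - 1
        b = i + 1 if i + 1 < k else spec.n_landmarks - 1 if spec.n_landmarks else i - 2
        neighbors[i] = (a, b)
    return gm.SlidingScheme(curve_neighbors=neighbors)


STAGES = ("simulate", "quantify", "align", "stats", "pls", "render")


def run_pipeline(config: AnalysisConfig, until: str = "render") -> dict:
    """Run the workflow up to and including stage ``until`` (default: all).

    Stages that need more than one region (ANOVA, Tukey) are skipped with a
    logged notice when only one region is configured.
    """
    if until not in STAGES and until != "all":
        raise ValueError(f"unknown stage {until!r}")
    last = len(STAGES) - 1 if until == "all" else STAGES.index(until)
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    def stage(name):
        log.info("stage %-10s starting", name)
        return time.time()

    def finalize() -> dict:
        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "config_hash": config.hash(),
                    "seed": config.seed,
                    "regions": list(config.regions),
                    "n_permutations": config.n_permutations,
                    "elapsed_s": round(time.time() - t_start, 3),
                },
                indent=1,
            )
            + "\n"
        )
        return bundle

    # ---- simulate -------------------------------------------------------
    t0 = stage("simulate")
    try:
        base_spec = CohortSpec(**config.cohort, seed=config.seed)
        study = generate_study(base_spec, regions=config.regions, seed=config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    bundle["study"] = study
    for region, cohort in study.items():
        io.write_grids_csv(
            {s.specimen_id: s.grid for s in cohort.specimens},
            out / f"grids_{region}.csv",
        )
        io.write_landmarks_csv(
            [s.landmarks for s in cohort.specimens], out / f"landmarks_{region}.csv"
        )
    io.write_manifest(
        out / "manifest.json",
        specimens={
            region: [
                {"specimen_id": s.specimen_id, "age_group": int(s.age_group)}
                for s in cohort.specimens
            ]
            for region, cohort in study.items()
        },
        seed=config.seed,
        truth_summary={
            region: {"target_mean_sizes": list(map(float, c.truth["target_mean_sizes"]))}
            for region, c in study.items()
        },
        extra={"config_hash": config.hash()},
    )
    log.info("stage simulate done in %.2fs (%d regions)", time.time() - t0, len(study))
    if last < STAGES.index("quantify"):
        return finalize()

    # ---- quantify -------------------------------------------------------
    t0 = stage("quantify")
    rows = []
    maps_by_region: dict[str, list[bm.ResorptionMap]] = {}
    for region, cohort in study.items():
        maps_by_region[region] = []
        for s in cohort.specimens:
            maps_by_region[region].append(bm.resorption_map(s.grid))
            rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "region": region,
                    "age_group": s.age_group,
                    "pct_br": bm.region_percent_resorption(s.grid),
                }
            )
    region_br = pd.DataFrame(rows)
    _write(region_br, out / "region_pct_br.csv", config)
    bundle["region_br"] = region_br

    summary = stats.region_resorption_summary(
        region_br["pct_br"], region_br["region"], region_br["age_group"]
    )
    _write(summary, out / "region_pct_br_summary.csv", config)
    bundle["region_br_summary"] = summary

    mean_maps = {}
    for region, cohort in study.items():
        ags = cohort.age_groups
        for g in sorted(set(ags)):
            mm = bm.mean_map(
                [m for m, a in zip(maps_by_region[region], ags) if a == g], g
            )
            mean_maps[(region, g)] = mm
            io.write_map_json(mm, out / f"mean_map_{region}_ag{g}.json")
    bundle["mean_maps"] = mean_maps
    log.info("stage quantify done in %.2fs (%d specimens)", time.time() - t0, len(rows))
    if last < STAGES.index("align"):
        return finalize()

    # ---- align (GPA + sliding) -----------------------------------------
    t0 = stage("align")
    aligned = {}
    for region, cohort in study.items():
        scheme = default_sliding_scheme(cohort.spec)
        configs = [s.landmarks for s in cohort.specimens]
        shapes, res = gm.slide_semilandmarks(
            configs, scheme, max_outer_iter=config.sliding_outer_iter, tol=config.gpa_tol
        )
        aligned[region] = (shapes, res)
    bundle["aligned"] = aligned
    log.info("stage align done in %.2fs", time.time() - t0)
    if last < STAGES.index("stats"):
        return finalize()

    # ---- growth / development stats ------------------------------------
    t0 = stage("stats")
    ss = np.random.SeedSequence(config.seed)
    growth_rows, perm_frames = [], []
    for region, cohort in study.items():
        shapes, res = aligned[region]
        ags = cohort.age_groups
        sizes = res.centroid_sizes
        mean_sizes = np.array([sizes[ags == g].mean() for g in range(1, 6)])
        mean_shapes = [shapes[ags == g].mean(axis=0) for g in range(1, 6)]
        growth = stats.relative_growth(mean_sizes, region=region)
        devel = stats.relative_development(mean_shapes, region=region)
        for kind, prof in (("growth", growth), ("development", devel)):
            for lab, absolute, rel in zip(
                prof.interval_labels, prof.absolute_differences, prof.relative_percent
            ):
                growth_rows.append(
                    {
                        "region": region,
                        "kind": kind,
                        "interval": lab,
                        "absolute": absolute,
                        "relative_percent": rel,
                    }
                )
        child = ss.spawn(1)[0]
        size_tab, shape_tab = stats.pairwise_permutation_tables(
            {g: sizes[ags == g] for g in range(1, 6)},
            {g: shapes[ags == g] for g in range(1, 6)},
            n_iter=config.n_permutations,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        sf = size_tab.to_frame().rename(
            columns={"statistic": "size_stat", "p_value": "size_p"}
        )
        hf = shape_tab.to_frame().rename(
            columns={"statistic": "shape_stat", "p_value": "shape_p"}
        )
        merged = sf.merge(hf, on=["group_a", "group_b"])
        merged.insert(0, "region", region)
        perm_frames.append(merged)
    growth_table = pd.DataFrame(growth_rows)
    _write(growth_table, out / "relative_growth_development.csv", config)
    perm_table = pd.concat(perm_frames, ignore_index=True)
    _write(perm_table, out / "permutation_tests.csv", config)
    bundle["growth_table"] = growth_table
    bundle["permutation_table"] = perm_table

    if len(config.regions) >= 2:
        f, p = stats.anova_region_resorption(region_br["pct_br"], region_br["region"])
        tukey = stats.tukey_hsd(region_br["pct_br"], region_br["region"])
        _write(pd.DataFrame([{"F": f, "p": p}]), out / "anova_region.csv", config)
        _write(tukey, out / "tukey_region.csv", config)
        bundle["anova"] = (f, p)
        bundle["tukey"] = tukey
    else:
        log.info("stage stats: ANOVA/Tukey skipped (needs >= 2 regions)")
    log.info("stage stats done in %.2fs", time.time() - t0)
    if last < STAGES.index("pls"):
        return finalize()

    # ---- PLS per region -------------------------------------------------
    t0 = stage("pls")
    pls_rows = []
    pls_results = {}
    for region, cohort in study.items():
        shapes, res = aligned[region]
        block = np.stack([m.values for m in maps_by_region[region]])
        child = ss.spawn(1)[0]
        try:
            pres = pls.pls_permutation_test(
                block,
                shapes.reshape(shapes.shape[0], -1),
                n_iter=config.n_permutations,
                seed=int(child.generate_state(1)[0] % (2**31)),
                na_policy=config.na_policy,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'pls' failed for region {region}: {exc}") from exc
        pls_results[region] = pres
        pls_rows.append(
            {
                "region": region,
                "pair": 1,
                "singular_value": pres.singular_values[0],
                "pct_total_covariance": pres.pct_total_covariance[0],
                "correlation_R": pres.score_correlation[0],
                "p_value": pres.p_values[0],
            }
        )
    pls_table = pd.DataFrame(pls_rows)
    _write(pls_table, out / "pls_region.csv", config)
    bundle["pls_table"] = pls_table
    bundle["pls_results"] = pls_results
    log.info("stage pls done in %.2fs", time.time() - t0)
    if last < STAGES.index("render"):
        return finalize()

    # ---- render ---------------------------------------------------------
    if config.render_meshes:
        t0 = stage("render")
        for (region, g), mm in mean_maps.items():
            mesh, assignment = io.grid_surface_mesh(mm.mean_values.size)
            values, flagged = bm.project_map_to_mesh(mm, len(mesh.vertices), assignment)
            io.write_colored_ply(mesh, values, flagged, out / f"mean_map_{region}_ag{g}.ply")
        log.info("stage render done in %.2fs", time.time() - t0)

    return finalize()
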
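"""Pipeline orchestration: simulate -> histories -> metrics -> fits -> report.

Each stage reads only files written by earlier stages (or package
fixtures), so a run is reproducible from its manifest: the manifest records
the seed, the full configuration, package version and a SHA-256 checksum of
every output. Re-running with the same configuration and seed yields
byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from . import __version__
from ._util import round_half_up
from .gridding import (
    EncounterHistory,
    build_checkerboard_grid,
    assign_replicates,
    build_encounter_history,
    dedupe_points,
    grid_to_geojson,
    points_to_geojson,
)
from .metrics import (
    TOTAL_DISTANCE_FLOWN_KM,
    cost_per_km,
    load_cost_models,
    summarize_missions,
    MissionRecord,
)
from .occupancy import (
    SingleModelSpec,
    aic_table,
    area_used,
    conditional_psi,
    fit as fit_single,
    naive_occupancy,
    percent_increase,
)
from .cooccurrence import compare_independence, fit_pair
from .synthetic import SyntheticConfig, simulate_survey, SPECIES_A, SPECIES_B

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "histories", "metrics", "fit_single", "fit_pair", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration: stages, synthetic-survey block, analysis options."""

    stages: tuple = ALL_STAGES
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    dedupe_radius_m: float = 5.0
    na_string: str = "NA"
    seed: int | None = None  # overrides synthetic.seed when set

    def __post_init__(self):
        if self.seed is not None:
            self.synthetic.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", {})
        for key in ("replicate_dist", "p_A", "p_B", "r_A", "r_B"):
            if syn.get(key) is not None:
                syn[key] = tuple(syn[key])
        cfg = cls(
            stages=tuple(raw.get("stages", ALL_STAGES)),
            synthetic=SyntheticConfig(**syn),
            dedupe_radius_m=float(raw.get("dedupe_radius_m", 5.0)),
            na_string=str(raw.get("na_string", "NA")),
            seed=seed if seed is not None else raw.get("seed"),
        )
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage '{stage}' requires missing input file: {path}")
    return path


# ------------------------------------------------------------------ stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    sim = simulate_survey(cfg.synthetic)
    written = []

    def w(path: Path):
        written.append(path)
        return path

    sim["points"].to_csv(w(out / "points.csv"), index=False)
    _write_json(points_to_geojson(sim["points"]), w(out / "points.geojson"))
    _write_json(grid_to_geojson(sim["grid"]), w(out / "grid.geojson"))
    ribbon = sim["ribbon"]
    _write_json(
        {
            "type": "Feature",
            "geometry": ribbon.__geo_interface__,
            "properties": {"role": "river_ribbon"},
        },
        w(out / "ribbon.geojson"),
    )
    _write_json(
        {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": p.__geo_interface__,
                 "properties": {"path_id": i}}
                for i, p in enumerate(sim["paths"])
            ],
        },
        w(out / "paths.geojson"),
    )
    for key, name in (("hist_A", SPECIES_A), ("hist_B", SPECIES_B), ("hist_combined", "combined")):
        sim[key].to_csv(w(out / f"hist_{name}.csv"), na_string=cfg.na_string)
    pd.DataFrame(
        {
            "cell_id": np.arange(sim["states"].n_cells),
            "n_replicates": sim["states"].n_replicates,
            "latent_state": sim["states"].states,
        }
    ).to_csv(w(out / "latent_states.csv"), index=False)
    pd.DataFrame([asdict(m) for m in sim["missions"]]).to_csv(
        w(out / "missions.csv"), index=False
    )
    return written


def stage_histories(cfg: PipelineConfig, out: Path) -> list[Path]:
    """Rebuild encounter histories from the point/geometry files alone."""
    stage = "histories"
    points = pd.read_csv(_require(out / "points.csv", stage))
    ribbon = shape(json.loads(_require(out / "ribbon.geojson", stage).read_text())["geometry"])
    paths_gj = json.loads(_require(out / "paths.geojson", stage).read_text())
    from shapely.geometry import LineString

    paths = [LineString(f["geometry"]["coordinates"]) for f in paths_gj["features"]]
    grid = build_checkerboard_grid(ribbon, cfg.synthetic.cell_size_m)
    rep_map = assign_replicates(paths, grid)
    deduped = dedupe_points(points, cfg.dedupe_radius_m)
    written = []
    deduped.to_csv(out / "points_deduped.csv", index=False)
    written.append(out / "points_deduped.csv")
    hists = {}
    for species in (SPECIES_A, SPECIES_B):
        hists[species] = build_encounter_history(deduped, grid, rep_map, species)
        path = out / f"hist_rebuilt_{species}.csv"
        hists[species].to_csv(path, na_string=cfg.na_string)
        written.append(path)
    combined = hists[SPECIES_A].union(hists[SPECIES_B])
    path = out / "hist_rebuilt_combined.csv"
    combined.to_csv(path, na_string=cfg.na_string)
    written.append(path)
    rep_rows = [
        {"cell_id": cid, "n_replicates": len(segs)} for cid, segs in sorted(rep_map.items())
    ]
    pd.DataFrame(rep_rows).to_csv(out / "replicate_map.csv", index=False)
    written.append(out / "replicate_map.csv")
    return written


def stage_metrics(cfg: PipelineConfig, out: Path) -> list[Path]:
    stage = "metrics"
    df = pd.read_csv(_require(out / "missions.csv", stage))
    records = [MissionRecord(**row) for row in df.to_dict("records")]
    summary = summarize_missions(records)
    written = []
    summary.table.to_csv(out / "mission_metrics.csv", index=False)
    written.append(out / "mission_metrics.csv")
    stats = pd.DataFrame(
        {
            "statistic": ["total"] * len(summary.totals) + ["mean"] * len(summary.means)
            + ["sd"] * len(summary.sds),
            "column": list(summary.totals) + list(summary.means) + list(summary.sds),
            "value": list(summary.totals.values()) + list(summary.means.values())
            + list(summary.sds.values()),
        }
    )
    stats.to_csv(out / "mission_summary_stats.csv", index=False)
    written.append(out / "mission_summary_stats.csv")
    cost_rows = []
    for stype, model in load_cost_models().items():
        dist = TOTAL_DISTANCE_FLOWN_KM if stype == "drone" else model.surveyed_distance_km
        cost_rows.append(
            {
                "survey_type": stype,
                "total_cost_usd": model.total_cost,
                "distance_km": dist,
                "cost_per_km": cost_per_km(model, dist),
            }
        )
    pd.DataFrame(cost_rows).to_csv(out / "cost_comparison.csv", index=False)
    written.append(out / "cost_comparison.csv")
    return written


def stage_fit_single(cfg: PipelineConfig, out: Path) -> list[Path]:
    stage = "fit_single"
    total_area = cfg.synthetic.n_cells * cfg.synthetic.cell_area_km2
    fit_rows, comp_frames = [], []
    cond_props: dict[int, dict] = {}
    for species in (SPECIES_A, SPECIES_B, "combined"):
        hist = EncounterHistory.from_csv(
            _require(out / f"hist_{species}.csv", stage), species, cfg.na_string
        )
        fits = []
        for structure in ("survey_specific", "constant"):
            f = fit_single(hist, SingleModelSpec(structure), seed=cfg.synthetic.seed)
            fits.append(f)
            row = {
                "species": species,
                "model": f.model,
                "psi": f.psi,
                "psi_se": f.psi_se,
                "log_lik": f.log_lik,
                "k": f.k,
                "aic": f.aic,
                "deviance": f.deviance,
                "naive": naive_occupancy(hist),
                "area_used_km2": area_used(f.psi, total_area),
                "converged": f.converged,
            }
            row["pct_increase_over_naive"] = percent_increase(f.psi, row["naive"])
            for j, (pj, sj) in enumerate(zip(f.p, f.p_se)):
                row[f"p{j + 1}"] = pj
                row[f"p{j + 1}_se"] = sj
            fit_rows.append(row)
        comp = aic_table(fits)
        comp.insert(0, "species", species)
        comp_frames.append(comp)
        best = min(fits, key=lambda f: f.aic)
        cond = conditional_psi(best, hist)
        for cid, c in zip(hist.cell_ids, cond):
            cond_props.setdefault(int(cid), {})[f"cond_psi_{species}"] = round(float(c), 4)
    written = []
    pd.DataFrame(fit_rows).to_csv(out / "single_species_fits.csv", index=False)
    written.append(out / "single_species_fits.csv")
    pd.concat(comp_frames, ignore_index=True).to_csv(out / "model_selection.csv", index=False)
    written.append(out / "model_selection.csv")
    grid_gj = json.loads(_require(out / "grid.geojson", stage).read_text())
    for feat in grid_gj["features"]:
        cid = feat["properties"]["cell_id"]
        feat["properties"].update(cond_props.get(cid, {}))
    _write_json(grid_gj, out / "conditional_psi.geojson")
    written.append(out / "conditional_psi.geojson")
    return written


def stage_fit_pair(cfg: PipelineConfig, out: Path) -> list[Path]:
    stage = "fit_pair"
    hist_a = EncounterHistory.from_csv(
        _require(out / f"hist_{SPECIES_A}.csv", stage), SPECIES_A, cfg.na_string
    )
    hist_b = EncounterHistory.from_csv(
        _require(out / f"hist_{SPECIES_B}.csv", stage), SPECIES_B, cfg.na_string
    )
    free = fit_pair(hist_a, hist_b, seed=cfg.synthetic.seed)
    indep = fit_pair(hist_a, hist_b, fix_phi=1, seed=cfg.synthetic.seed)
    comp = compare_independence(free, indep)
    rows = []
    for f in (free, indep):
        row = {
            "model": f.label, "psi_A": f.psi_A, "psi_B": f.psi_B, "phi": f.phi,
            "psi_AB": f.psi_AB, "p_A": f.p_A, "p_B": f.p_B, "r_A": f.r_A, "r_B": f.r_B,
            "delta": f.delta, "phi_ci_low": f.phi_ci[0], "phi_ci_high": f.phi_ci[1],
            "log_lik": f.log_lik, "k": f.k, "aic": f.aic, "deviance": f.deviance,
            "converged": f.converged,
        }
        row.update({f"se_{k}": v for k, v in f.se.items()})
        rows.append(row)
    written = []
    pd.DataFrame(rows).to_csv(out / "pair_fits.csv", index=False)
    written.append(out / "pair_fits.csv")
    comp.table.to_csv(out / "pair_model_selection.csv", index=False)
    written.append(out / "pair_model_selection.csv")
    _write_json(
        {
            "delta_aic": comp.delta_aic,
            "weight_free": comp.weight_free,
            "weight_phi1": comp.weight_phi1,
            "competing": comp.competing,
            "verdict": comp.verdict,
        },
        out / "independence_verdict.json",
    )
    written.append(out / "independence_verdict.json")
    return written


def make_report(out: Path, na_string: str = "NA") -> list[Path]:
    """Assemble report tables in the layout of the published summary tables.

    Emits a mission table with a recomputed totals/means row, the
    model-selection table, the cost comparison, and leaves the
    conditional-occupancy GeoJSON layer as the map analog.
    """
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    written = []
    metrics_path = out / "mission_metrics.csv"
    if metrics_path.exists():
        df = pd.read_csv(metrics_path)
        cols = ["distance_km", "flight_min", "surface_km2", "photo_count", "count_A", "count_B"]
        total = {c: df[c].sum() for c in cols}
        total.update(
            {
                "mission_id": "Total",
                "rai_A": round_half_up(df["rai_A"].mean(), 2),
                "rai_B": round_half_up(df["rai_B"].mean(), 2),
                "od_A": round_half_up(df["od_A"].mean(), 2),
                "od_B": round_half_up(df["od_B"].mean(), 2),
            }
        )
        table1 = pd.concat([df.round(2), pd.DataFrame([total])], ignore_index=True)
        table1.to_csv(report_dir / "table_missions.csv", index=False)
        written.append(report_dir / "table_missions.csv")
    sel_frames = []
    for name in ("model_selection.csv", "pair_model_selection.csv"):
        if (out / name).exists():
            sel_frames.append(pd.read_csv(out / name))
    if sel_frames:
        pd.concat(sel_frames, ignore_index=True).round(2).to_csv(
            report_dir / "table_model_selection.csv", index=False
        )
        written.append(report_dir / "table_model_selection.csv")
    if (out / "cost_comparison.csv").exists():
        pd.read_csv(out / "cost_comparison.csv").to_csv(
            report_dir / "table_costs.csv", index=False
        )
        written.append(report_dir / "table_costs.csv")
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "histories": stage_histories,
    "metrics": stage_metrics,
    "fit_single": stage_fit_single,
    "fit_pair": stage_fit_pair,
}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    On stage failure the partial outputs of that stage are renamed with a
    ``.partial`` suffix and a StageError naming the stage is raised.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.synthetic.seed,
        "version": __version__,
        "config": {
            "stages": list(cfg.stages),
            "dedupe_radius_m": cfg.dedupe_radius_m,
            "na_string": cfg.na_string,
            "synthetic": asdict(cfg.synthetic),
        },
        "stages_run": [],
        "outputs": {},
    }
    for stage in cfg.stages:
        if stage == "report":
            written = make_report(out, cfg.na_string)
        else:
            func = _STAGE_FUNCS.get(stage)
            if func is None:
                raise StageError(f"unknown stage '{stage}'")
            before = {p: p.stat().st_mtime_ns for p in out.glob("*")}
            try:
                written = func(cfg, out)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                for p in out.glob("*"):
                    if p.suffix != ".partial" and before.get(p) != p.stat().st_mtime_ns:
                        p.rename(p.with_suffix(p.suffix + ".partial"))
                raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages_run"].append(stage)
        for p in written:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        logger.info("stage %s wrote %d files", stage, len(written))
    _write_json(manifest, out / "manifest.json")
    return manifest
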
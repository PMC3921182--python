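"""End-to-end orchestration: fixes -> home ranges -> ln(rf) -> models.

Stages mirror the analysis order: ingest and filter fixes, estimate the
monthly kernel UDs and 99% home ranges with the ad-hoc bandwidth rule,
compute habitat- and ecoregion-scale selection ratios, attach zonal
monthly meteorology, fit the repeated-measures models, and write report
tables and figures.  Every stage writes plain-text outputs into the run
directory and the manifest records row counts and checksums, so a rerun
with the same configuration is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ingest, kernel, selection
from .grids import PolygonLayer, Raster
from .met import MET_PARAMETERS, met_wide, zonal_means
from .models import (
    ModelSpec,
    ecoregion_model_average,
    fit_mixed_ar1,
    independent_terms,
    screen_effects,
)

logger = logging.getLogger(__name__)

STAGES = ("ingest", "ud", "select", "met", "model", "report")

BIRD_TERMS = ["sex", "age_class", "breeder", "release_site", "rearing"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips through JSON unchanged."""

    fixes: str
    attributes: str
    habitat_raster: str
    ecoregions: str
    met_table: str = ""
    met_cells: str = ""
    outdir: str = "soarsel_run"
    cell: float = 100.0
    isopleth_level: float = 0.99
    min_fixes: int = 100
    tz_offset_hours: float = 0.0
    global_multiplier: float | None = None
    use_estimator: str = "ud"
    alpha: float = 0.01
    seed: int = 0
    base_terms: list[str] = field(default_factory=lambda: list(BIRD_TERMS))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _usable_terms(data: pd.DataFrame, terms: list[str]) -> list[str]:
    """Drop aliased terms (single-level factors, constant covariates)."""
    out = []
    for t in terms:
        cols = t.split(":")
        if all(data[c].nunique(dropna=True) > 1 for c in cols if c in data.columns):
            out.append(t)
    return out


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> dict:
    """Run the pipeline, returning the manifest (also written to disk)."""
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; stages are {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "files": {}}

    def record(stage: str, name: str, n_rows: int | None = None) -> None:
        path = outdir / name
        manifest["files"][name] = {"sha256": _sha256(path)}
        if n_rows is not None:
            manifest["files"][name]["rows"] = n_rows
        manifest["stages"].setdefault(stage, []).append(name)

    def finish(stage: str) -> bool:
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return stop_after == stage

    # ---- ingest ----------------------------------------------------------
    fixes = ingest.read_fixes(config.fixes)
    attrs = ingest.read_attributes(config.attributes)
    fixes = ingest.window_filter(fixes, tz_offset_hours=config.tz_offset_hours)
    panels = ingest.build_panels(fixes, min_fixes=config.min_fixes)
    if not panels:
        raise RuntimeError("stage ingest: no bird-month panel passed the fix filter")
    panel_table = pd.DataFrame(
        [{"bird_id": p.bird_id, "year": p.year, "month": p.month,
          "n_fixes": p.n_fixes} for p in panels]
    )
    panel_table.to_csv(outdir / "panels.csv", index=False)
    record("ingest", "panels.csv", len(panel_table))
    if finish("ingest"):
        return manifest

    # ---- utilization distributions / home ranges -------------------------
    habitat = Raster.read_ascii(config.habitat_raster)
    ecoregions = PolygonLayer.read_geojson(config.ecoregions)
    uds, hrs, bw_rows = {}, {}, []
    for p in panels:
        key = (p.bird_id, p.year, p.month)
        try:
            if config.global_multiplier is not None:
                h_ref = kernel.reference_bandwidth(p.points)
                ud = kernel.kernel_ud(p.points, config.global_multiplier * h_ref,
                                      cell=config.cell, h_ref=h_ref)
                hr = kernel.volume_isopleth(ud, config.isopleth_level)
                m = config.global_multiplier
            else:
                m, ud, hr = kernel.select_adhoc_bandwidth(
                    p.points, level=config.isopleth_level, cell=config.cell
                )
        except (kernel.NoContiguousSolutionError, kernel.DegenerateSpreadError) as err:
            raise RuntimeError(
                f"stage ud: panel {key} failed bandwidth selection: {err}"
            ) from err
        uds[key], hrs[key] = ud, hr
        bw_rows.append(
            {"bird_id": p.bird_id, "year": p.year, "month": p.month,
             "n_fixes": p.n_fixes, "h_ref": ud.h_ref, "multiplier": m,
             "h": ud.h, "mass": hr.mass, "n_components": hr.n_components,
             "area_km2": hr.area_m2 / 1e6}
        )
    pd.DataFrame(bw_rows).to_csv(outdir / "bandwidths.csv", index=False)
    record("ud", "bandwidths.csv", len(bw_rows))
    if finish("ud"):
        return manifest

    # ---- selection ratios -------------------------------------------------
    hab_records, eco_records = [], []
    for p in panels:
        key = (p.bird_id, p.year, p.month)
        ud, hr = uds[key], hrs[key]
        hab_records.extend(
            selection.habitat_panel(
                ud, hr, habitat, p.bird_id, p.year, p.month,
                points=p.points, use_estimator=config.use_estimator,
            )
        )
        eco_records.extend(
            selection.ecoregion_panel(ud, hr, ecoregions, p.bird_id, p.year, p.month)
        )
    hab_df = selection.records_to_frame(hab_records)
    eco_df = selection.records_to_frame(eco_records)
    hab_df.to_csv(outdir / "selection_habitat.csv", index=False)
    eco_df.to_csv(outdir / "selection_ecoregion.csv", index=False)
    record("select", "selection_habitat.csv", len(hab_df))
    record("select", "selection_ecoregion.csv", len(eco_df))
    if finish("select"):
        return manifest

    # ---- meteorology -------------------------------------------------------
    eco_met = pd.DataFrame()
    if config.met_table and config.met_cells:
        met_table = pd.read_csv(config.met_table)
        cells = PolygonLayer.read_geojson(config.met_cells)
        zonal = zonal_means(met_table, cells, ecoregions)
        zonal.to_csv(outdir / "met_zonal.csv", index=False)
        record("met", "met_zonal.csv", len(zonal))
        eco_met = met_wide(zonal)
    if finish("met"):
        return manifest

    # ---- models ------------------------------------------------------------
    hab_model = hab_df.dropna(subset=["ln_rf"]).merge(attrs, on="bird_id")
    test_rows = []
    for unit, grp in hab_model.groupby("unit"):
        terms = independent_terms(grp, _usable_terms(grp, config.base_terms))
        if not terms or grp["bird_id"].nunique() < 2:
            logger.info("habitat class %s skipped (insufficient variation)", unit)
            continue
        try:
            fit = fit_mixed_ar1(grp, ModelSpec(terms), method="reml")
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("habitat class %s model failed: %s", unit, err)
            continue
        for _, row in fit.wald_tests().iterrows():
            test_rows.append({"habitat": unit, **row.to_dict()})
    test_columns = ["habitat", "term", "F", "df_num", "df_den", "p"]
    hab_tests = pd.DataFrame(test_rows, columns=None if test_rows else test_columns)
    hab_tests = screen_effects(hab_tests, alpha=config.alpha)
    hab_tests.to_csv(outdir / "habitat_effect_tests.csv", index=False)
    record("model", "habitat_effect_tests.csv", len(hab_tests))

    avg_rows, rank_lines = [], []
    if not eco_met.empty:
        eco_model = (
            eco_df.dropna(subset=["ln_rf"])
            .merge(attrs, on="bird_id")
            .merge(eco_met, left_on=["unit", "year", "month"],
                   right_on=["ecoregion", "year", "month"])
        )
        for eco, grp in eco_model.groupby("unit"):
            # month is excluded from the met model base: with monthly
            # climatological covariates a categorical month term aliases them
            base = independent_terms(grp, _usable_terms(grp, config.base_terms))
            met_terms = tuple(
                independent_terms(
                    grp, base + _usable_terms(grp, list(MET_PARAMETERS))
                )[len(base):]
            )
            if grp["bird_id"].nunique() < 2 or not met_terms:
                logger.info("ecoregion %s skipped (insufficient data)", eco)
                continue
            try:
                result = ecoregion_model_average(grp, base, met_terms)
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.warning("ecoregion %s model set failed: %s", eco, err)
                continue
            for param in MET_PARAMETERS:
                ma = result["averages"].get(param)
                if ma is None:
                    avg_rows.append({"ecoregion": eco, "parameter": param,
                                     "estimate": 0.0, "ci_low": 0.0, "ci_high": 0.0,
                                     "unconditional_se": 0.0, "importance": 0.0})
                else:
                    avg_rows.append({"ecoregion": eco, "parameter": ma.parameter,
                                     "estimate": ma.estimate, "ci_low": ma.ci_low,
                                     "ci_high": ma.ci_high,
                                     "unconditional_se": ma.unconditional_se,
                                     "importance": ma.importance})
            rank_lines.append(f"# ecoregion {eco}")
            rank_lines.append(result["ranking"].to_string(index=False))
            rank_lines.append("")
    avg_columns = ["ecoregion", "parameter", "estimate", "ci_low", "ci_high",
                   "unconditional_se", "importance"]
    pd.DataFrame(avg_rows, columns=None if avg_rows else avg_columns).to_csv(
        outdir / "ecoregion_model_averages.csv", index=False)
    record("model", "ecoregion_model_averages.csv", len(avg_rows))
    (outdir / "model_ranking.txt").write_text("\n".join(rank_lines))
    record("model", "model_ranking.txt")
    if finish("model"):
        return manifest

    # ---- report ------------------------------------------------------------
    figures = make_report(outdir)
    for name in figures:
        record("report", name)
    finish("report")
    return manifest


def make_report(outdir: str | Path) -> list[str]:
    """Figures from stage outputs: monthly ln(rf) curves per habitat, a
    forest plot of model-averaged met effects, and monthly ln(rf) ranges."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    made = []
    hab_path = outdir / "selection_habitat.csv"
    if not hab_path.exists():
        raise FileNotFoundError(
            "selection_habitat.csv missing; run the selection stage first"
        )
    hab = pd.read_csv(hab_path).dropna(subset=["ln_rf"])

    units = sorted(hab["unit"].unique())
    ncols = min(4, len(units))
    nrows = int(np.ceil(len(units) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False, sharex=True)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for i, unit in enumerate(units):
        ax = axes[i // ncols][i % ncols]
        g = hab[hab["unit"] == unit].groupby("month")["ln_rf"]
        mean, sem = g.mean(), g.sem().fillna(0.0)
        ax.axhline(0, color="grey", lw=0.6)
        ax.errorbar(mean.index, mean, yerr=1.96 * sem, fmt="o-", ms=3, lw=1)
        label = selection.HABITAT_CLASS_NAMES.get(int(unit), str(unit))
        ax.set_title(f"{letters[i % 26]} = {label}", fontsize=8)
    for j in range(len(units), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.supxlabel("month")
    fig.supylabel("ln(rf)")
    fig.tight_layout()
    fig.savefig(outdir / "habitat_selection_by_month.png", dpi=120)
    plt.close(fig)
    made.append("habitat_selection_by_month.png")

    avg_path = outdir / "ecoregion_model_averages.csv"
    if avg_path.exists():
        avg = pd.read_csv(avg_path)
        if not avg.empty:
            fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
            for ax, param in zip(axes, sorted(avg["parameter"].unique())):
                sub = avg[avg["parameter"] == param]
                y = np.arange(len(sub))
                ax.errorbar(sub["estimate"], y,
                            xerr=[sub["estimate"] - sub["ci_low"],
                                  sub["ci_high"] - sub["estimate"]],
                            fmt="o", ms=3)
                ax.axvline(0, color="grey", lw=0.6)
                ax.set_yticks(y, [str(e) for e in sub["ecoregion"]])
                ax.set_title(param, fontsize=9)
            axes[0].set_ylabel("ecoregion")
            fig.tight_layout()
            fig.savefig(outdir / "ecoregion_met_effects.png", dpi=120)
            plt.close(fig)
            made.append("ecoregion_met_effects.png")
        else:
            logger.info("ecoregion model-average table empty; forest plot skipped")

    rng_stats = hab.groupby("unit")["ln_rf"].agg(["min", "max", "mean"])
    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(rng_stats))
    ax.vlines(x, rng_stats["min"], rng_stats["max"], lw=2, alpha=0.6)
    ax.plot(x, rng_stats["mean"], "o", ms=4)
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_xticks(x, [str(u) for u in rng_stats.index], rotation=45)
    ax.set_ylabel("monthly ln(rf) range")
    fig.tight_layout()
    fig.savefig(outdir / "monthly_lnrf_ranges.png", dpi=120)
    plt.close(fig)
    made.append("monthly_lnrf_ranges.png")
    return made


def write_scenario(scenario, outdir: str | Path, n_classes: int | None = None,
                   patch_scale: float = 2000.0, n_ecoregions: int = 4) -> dict:
    """Generate and serialize a complete synthetic study to ``outdir``.

    Writes fixes.csv, birds.csv, habitat.asc, ecoregions.geojson, met.csv,
    met_cells.geojson, and ground_truth.json; returns the file map.
    """
    from . import synthetic

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_classes = len(scenario.habitat_weights) if n_classes is None else n_classes
    habitat, ecoregions = synthetic.generate_landscape(
        scenario.seed, scenario.extent, n_classes=n_classes,
        patch_scale=patch_scale, n_ecoregions=n_ecoregions,
    )
    met_table, met_cells = synthetic.generate_met_grid(
        scenario.seed, scenario.extent, scenario.months, scenario.met_params
    )
    fixes, attrs, truth = synthetic.simulate_tracks(scenario, habitat)

    fixes.to_csv(outdir / "fixes.csv", index=False)
    attrs.to_csv(outdir / "birds.csv", index=False)
    habitat.write_ascii(outdir / "habitat.asc")
    ecoregions.write_geojson(outdir / "ecoregions.geojson")
    met_table.to_csv(outdir / "met.csv", index=False)
    met_cells.write_geojson(outdir / "met_cells.geojson")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "expected_lnrf": {str(k): v for k, v in truth.expected_lnrf.items()},
                "availability": {str(k): v for k, v in truth.availability.items()},
            },
            fh, indent=2,
        )
    return {
        "fixes": str(outdir / "fixes.csv"),
        "attributes": str(outdir / "birds.csv"),
        "habitat_raster": str(outdir / "habitat.asc"),
        "ecoregions": str(outdir / "ecoregions.geojson"),
        "met_table": str(outdir / "met.csv"),
        "met_cells": str(outdir / "met_cells.geojson"),
    }
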
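"""End-to-end orchestration: simulate → risk → water → map → stats.

One YAML/JSON run configuration drives every stage. Stages are
independent: a stage runs whenever its inputs are present, one failing
stage does not abort the others, and the bundle's summary JSON indexes
every produced output together with the per-stage status.
"""

from __future__ import annotations

import json
import logging
import traceback
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __name__ as _pkg
from .data_model import (
    ConcentrationTable,
    ExposureScenario,
    RiskReport,
    ToxParamRegistry,
    read_concentration_table,
    write_concentration_table,
    write_report,
)
from .dietary import DietaryRiskAssessor, screen_mpl
from .geospatial import idw_grid, write_raster
from .multivariate import CorrelationPCA, gate_for_pca, pearson_matrix, ward_cluster
from .synthetic import SyntheticSpec, generate
from .water import WaterQualityIndexer, radar_summary

log = logging.getLogger("ptesrisk")


class IdwSettings(BaseModel):
    power: float = 2.0
    max_neighbors: int | None = None
    cell_size: float = 0.05
    n_rows: int = 40
    n_cols: int = 60
    elements: list[str] | None = None  # None → all


class StatsSettings(BaseModel):
    k_elements: int = 2
    k_stations: int = 2
    ridge: float = 0.0


class ScenarioSettings(BaseModel):
    ingestion_rate: float = 0.055
    body_weight: float = 70.0
    exposure_frequency: float | None = None
    exposure_duration: float | None = None
    averaging_time: float | None = None

    def build(self) -> ExposureScenario:
        return ExposureScenario(**self.model_dump())


class RunConfig(BaseModel):
    """Validated run configuration (YAML or JSON on disk)."""

    fish: str | None = None
    water: str | None = None
    params: str | None = None          # tox parameter CSV; packaged defaults if None
    scenario: ScenarioSettings = Field(default_factory=ScenarioSettings)
    authority: str = "fao"
    nondetect_policy: str = "lod_half"
    simulate: bool = False             # generate inputs instead of reading them
    seed: int = 0
    idw: IdwSettings = Field(default_factory=IdwSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    out_dir: str = "ptes_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data or {})


def _load_tables(config: RunConfig) -> tuple[ConcentrationTable | None,
                                             ConcentrationTable | None]:
    if config.simulate:
        return generate(SyntheticSpec(seed=config.seed))
    fish = water = None
    if config.fish:
        fish = read_concentration_table(
            config.fish, "fish", nondetect_policy=config.nondetect_policy)
    if config.water:
        water = read_concentration_table(
            config.water, "water", nondetect_policy=config.nondetect_policy)
    return fish, water


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage whose inputs are present.

    Returns the report bundle: per-stage status, output paths, and the
    key numbers (flags, index classes, PCA retention) the digest projects.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = (ToxParamRegistry.from_csv(config.params)
                if config.params else ToxParamRegistry.default())
    try:
        pkg_version = version("ptesrisk")
    except PackageNotFoundError:
        pkg_version = "unknown"
    bundle: dict[str, Any] = {
        "version": pkg_version,
        "seed": config.seed,
        "params_source": config.params or "packaged defaults",
        "stages": {},
        "outputs": {},
    }

    fish, water = _load_tables(config)
    if config.simulate:
        for tbl, name in ((fish, "fish"), (water, "water")):
            p = out_dir / f"synthetic_{name}.csv"
            write_concentration_table(tbl, p)
            bundle["outputs"][f"synthetic_{name}"] = str(p)

    def stage(name, fn, *, needs):
        missing = [n for n, obj in needs.items() if obj is None]
        if missing:
            bundle["stages"][name] = {
                "status": "skipped", "reason": f"missing inputs: {missing}"}
            log.info("stage %s skipped (missing %s)", name, missing)
            return
        try:
            fn()
            bundle["stages"][name] = {"status": "ok"}
            log.info("stage %s ok", name)
        except Exception as err:  # stage isolation is the contract
            bundle["stages"][name] = {
                "status": "error", "error": f"{type(err).__name__}: {err}"}
            log.error("stage %s failed:\n%s", name, traceback.format_exc())

    def _risk():
        assessor = DietaryRiskAssessor(
            registry=registry, scenario=config.scenario.build())
        report = assessor.assess(fish, water)
        write_report(report, out_dir / "risk_report.csv", "csv")
        write_report(report, out_dir / "risk_report.json", "json")
        screen = screen_mpl(fish.element_means(), registry, config.authority)
        screen.to_csv(out_dir / f"mpl_screen_{config.authority}.csv")
        bundle["outputs"]["risk_report"] = str(out_dir / "risk_report.csv")
        bundle["outputs"]["mpl_screen"] = str(
            out_dir / f"mpl_screen_{config.authority}.csv")
        ps = report.per_station
        bundle["dietary"] = {
            "stations": list(ps.index),
            "mpi": ps["mpi"].to_dict(),
            "hi": ps["hi"].to_dict(),
            "tcr": ps["tcr"].to_dict(),
            "hi_flagged": ps.index[ps["hi_flag"]].tolist(),
            "mpi_flagged": ps.index[ps["mpi_flag"]].tolist(),
            "tcr_band": ps["tcr_band"].to_dict(),
            "mpl_exceedances": screen.index[screen["exceeds"]].tolist(),
        }

    def _water():
        indexer = WaterQualityIndexer(registry=registry).fit(water)
        result = indexer.result_
        result.to_csv(out_dir / "water_indices.csv")
        radar_summary(result).to_csv(out_dir / "water_radar.csv", index=False)
        bundle["outputs"]["water_indices"] = str(out_dir / "water_indices.csv")
        bundle["outputs"]["water_radar"] = str(out_dir / "water_radar.csv")
        bundle["water"] = {
            col: result[col].to_dict()
            for col in ("wqi", "wqi_class", "hpi", "hpi_class", "hei", "hei_class")
        }

    def _map():
        wrote = []
        for tbl in (fish, water):
            if tbl is None or tbl.coordinates is None:
                continue
            xmin = tbl.coordinates["x"].min()
            ymin = tbl.coordinates["y"].min()
            elements = config.idw.elements or tbl.elements
            for el in elements:
                raster = idw_grid(
                    tbl, el, origin=(xmin, ymin),
                    cell_size=config.idw.cell_size,
                    n_rows=config.idw.n_rows, n_cols=config.idw.n_cols,
                    power=config.idw.power,
                    max_neighbors=config.idw.max_neighbors)
                p = out_dir / f"idw_{tbl.medium}_{el}.asc"
                write_raster(raster, p)
                wrote.append(str(p))
        if not wrote:
            raise ValueError("no table with coordinates available for mapping")
        bundle["outputs"]["rasters"] = wrote

    def _stats():
        bundle["stats"] = {}
        for tbl in (fish, water):
            if tbl is None:
                continue
            prefix = tbl.medium
            corr = pearson_matrix(tbl)
            corr.to_csv(out_dir / f"{prefix}_correlation.csv")
            gate = gate_for_pca(tbl, ridge=config.stats.ridge)
            model = CorrelationPCA().fit(tbl)
            res = model.result()
            res.loadings.to_csv(out_dir / f"{prefix}_pca_loadings.csv")
            variance = {
                "eigenvalues": res.eigenvalues.tolist(),
                "explained_pct": res.explained_pct.tolist(),
                "cum_explained_pct": res.cum_explained_pct.tolist(),
                "n_retained": res.n_retained,
            }
            clus_el = ward_cluster(tbl, "elements", config.stats.k_elements)
            clus_st = ward_cluster(tbl, "stations", config.stats.k_stations)
            clus_el.heat_matrix.to_csv(out_dir / f"{prefix}_heatmatrix.csv")
            gate_doc = {
                "kmo": gate.kmo, "bartlett_chi2": gate.bartlett_chi2,
                "bartlett_df": gate.bartlett_df, "bartlett_p": gate.bartlett_p,
                "passed": gate.passed,
            }
            (out_dir / f"{prefix}_kmo_bartlett.json").write_text(
                json.dumps(gate_doc, indent=2))
            bundle["stats"][prefix] = {
                "gate": gate_doc,
                "pca": variance,
                "element_clusters": {str(k): v for k, v in clus_el.groups().items()},
                "station_clusters": {str(k): v for k, v in clus_st.groups().items()},
            }
            bundle["outputs"][f"{prefix}_correlation"] = str(
                out_dir / f"{prefix}_correlation.csv")

    stage("dietary_risk", _risk, needs={"fish": fish})
    stage("water_quality", _water, needs={"water": water})
    stage("geospatial", _map, needs={"fish or water": fish or water})
    stage("multivariate", _stats, needs={"fish or water": fish or water})

    bundle["exit_status"] = int(any(
        s["status"] == "error" for s in bundle["stages"].values()))
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(bundle, indent=2, default=str))
    bundle["outputs"]["summary"] = str(summary_path)
    return bundle


def summarize(bundle: dict[str, Any]) -> str:
    """One-page digest of a report bundle — a pure projection, nothing
    is recomputed. Stations appear in input order."""
    lines = ["PTEs risk assessment digest", "=" * 28]
    for name, st in bundle.get("stages", {}).items():
        extra = st.get("reason") or st.get("error") or ""
        lines.append(f"stage {name}: {st['status']}" + (f" ({extra})" if extra else ""))
    d = bundle.get("dietary")
    if d:
        lines.append("")
        lines.append("Dietary risk (fish consumption):")
        flagged = d["hi_flagged"]
        lines.append(
            f"  HI > 1 at: {', '.join(flagged) if flagged else 'no stations'}")
        mpif = d["mpi_flagged"]
        lines.append(
            f"  MPI > 1 at: {', '.join(mpif) if mpif else 'no stations'}")
        sig = [s for s, b in d["tcr_band"].items() if b == "significant"]
        lines.append(
            f"  TCR significant (>1e-4) at: {', '.join(sig) if sig else 'no stations'}")
        exc = d.get("mpl_exceedances", [])
        lines.append(
            f"  MPL exceedances: {', '.join(exc) if exc else 'none'}")
        if not (flagged or mpif or sig or exc):
            lines.append("  no flags")
    w = bundle.get("water")
    if w:
        lines.append("")
        lines.append("Water quality classes per station:")
        for st in w["wqi"]:
            lines.append(
                f"  {st}: WQI {w['wqi'][st]:.1f} ({w['wqi_class'][st]}), "
                f"HPI {w['hpi'][st]:.1f} ({w['hpi_class'][st]}), "
                f"HEI {w['hei'][st]:.2f} ({w['hei_class'][st]})")
    s = bundle.get("stats")
    if s:
        for medium, doc in s.items():
            lines.append("")
            lines.append(
                f"{medium.capitalize()} PCA: {doc['pca']['n_retained']} components "
                f"with eigenvalue > 1, "
                f"{doc['pca']['cum_explained_pct'][doc['pca']['n_retained'] - 1]:.1f}% "
                f"of variance; gate "
                f"{'passed' if doc['gate']['passed'] else 'failed'} "
                f"(KMO {doc['gate']['kmo']:.2f}, "
                f"Bartlett p {doc['gate']['bartlett_p']:.2g})")
    return "\n".join(lines) + "\n"
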
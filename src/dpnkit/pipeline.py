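"""End-to-end pipeline: ingest → five DPNs → metrics → φ analysis → strata.

One :class:`RunConfig` (loadable from YAML) drives the whole run; all
randomness (only the simulator is stochastic — the analysis itself is
deterministic) flows from its single seed.  Every stage logs record /
node / edge counts and the run emits a manifest with a config hash so
it can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ingest, metrics, network, simulate, strata
from .phi import DegenerateFitError, analyse as phi_analyse, default_grid as phi_default_grid

__all__ = ["RunConfig", "load_config", "run_all"]

log = logging.getLogger("dpnkit")

DEFAULT_INDEX_DATE = _dt.date(2019, 6, 30)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (a records CSV) or ``sim`` (a
    simulation block) must be given.
    """

    seed: int
    input_path: str | None = None
    sim: simulate.SimConfig | None = None
    columns: dict | None = None
    birth_year_range: tuple[int, int] = (1919, 2019)
    index_date: _dt.date = DEFAULT_INDEX_DATE
    age_bins: tuple = ingest.DEFAULT_AGE_BINS
    weighting: str = "cij"
    grid_points: int = 50
    grid_min: float = 1e-5
    grid_max: float = 1.0
    cluster_k: int | None = None  # None = silhouette-chosen
    strata_levels: tuple[int, ...] = (1, 3, 5)
    outdir: str = "dpn_out"

    def __post_init__(self):
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be set")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["index_date"] = self.index_date.isoformat()
        return d


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("sim", None)
    if sim is not None:
        modules = tuple(
            simulate.ModuleSpec(codes=tuple(m["codes"]), boost=m["boost"],
                                share=m.get("share", 0.1))
            for m in sim.pop("modules", [])
        )
        sim = simulate.SimConfig(modules=modules, **sim)
    if "index_date" in raw:
        raw["index_date"] = _dt.date.fromisoformat(raw["index_date"])
    if "birth_year_range" in raw:
        raw["birth_year_range"] = tuple(raw["birth_year_range"])
    if "age_bins" in raw:
        raw["age_bins"] = tuple((lo, hi) for lo, hi in raw["age_bins"])
    if "strata_levels" in raw:
        raw["strata_levels"] = tuple(raw["strata_levels"])
    return RunConfig(sim=sim, **raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> Path:
    """Execute the full pipeline and return the artifact directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_jsonable(), "config_hash": _config_hash(cfg),
                      "seed": cfg.seed, "stages": {}, "outputs": []}
    try:
        _run_stages(cfg, outdir, manifest)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {manifest.get('_stage', '?')}: {exc}"
        _write_manifest(outdir, manifest)
        raise
    _write_manifest(outdir, manifest)
    return outdir


def _emit(outdir: Path, manifest: dict, name: str):
    manifest["outputs"].append(name)
    return outdir / name


def _run_stages(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    manifest["_stage"] = "ingest"
    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        records = simulate.generate_records(sim_cfg)
        load_report = ingest.FilterReport(
            records_in=len(records), records_out=len(records),
            patients_in=len({r.patient_id for r in records}),
            patients_out=len({r.patient_id for r in records}),
        )
    else:
        records, load_report = ingest.load_records(cfg.input_path, columns=cfg.columns)
    records, by_report = ingest.filter_birth_year(records, *cfg.birth_year_range)
    log.info("ingest: %d records, %d patients after filters",
             len(records), len({r.patient_id for r in records}))
    manifest["stages"]["ingest"] = {
        "load": load_report.to_dict(), "birth_year": by_report.to_dict(),
    }
    (_emit(outdir, manifest, "filter_report.json")).write_text(
        json.dumps(manifest["stages"]["ingest"], indent=2)
    )

    manifest["_stage"] = "demography"
    patients_tbl, rx_tbl, _ = ingest.demography_table(records, cfg.index_date, cfg.age_bins)
    patients_tbl.to_csv(_emit(outdir, manifest, "demography_patients.csv"), index=False)
    rx_tbl.to_csv(_emit(outdir, manifest, "demography_prescriptions.csv"), index=False)

    summary_rows = []
    grid = phi_default_grid(cfg.grid_points, cfg.grid_min, cfg.grid_max)
    for level in range(5, 0, -1):
        manifest["_stage"] = f"level-{level}"
        if not records:
            continue
        inc = ingest.build_incidence(records, level)
        dpn = network.build_dpn(inc)
        log.info("level %d: N=%d E=%d", level, dpn.N, dpn.E)
        network.write_graph(dpn, _emit(outdir, manifest, f"dpn_atcl{level}.graphml"))
        network.write_graph(dpn, _emit(outdir, manifest, f"dpn_atcl{level}.edges.csv"),
                            format="edgelist")
        manifest["outputs"].append(f"dpn_atcl{level}.edges.nodes.csv")
        nm = metrics.node_metrics(dpn, cfg.weighting)
        network.node_table(dpn, nm).to_csv(
            _emit(outdir, manifest, f"node_table_atcl{level}.csv"), index=False)
        summary_rows.append(metrics.summary(dpn, cfg.weighting).to_dict())

        try:
            curve = phi_analyse(dpn, grid)
        except (ValueError, DegenerateFitError) as exc:
            log.warning("level %d: φ analysis skipped (%s)", level, exc)
            continue
        pd.DataFrame({
            "phi_star": curve.grid, "node_frac": curve.node_frac,
            "edge_frac": curve.edge_frac,
        }).to_csv(_emit(outdir, manifest, f"retention_atcl{level}.csv"), index=False)
        fits = {
            "node_fit": dataclasses.asdict(curve.node_fit),
            "edge_fit": dataclasses.asdict(curve.edge_fit),
            "phi_max": curve.phi_max,
        }
        (_emit(outdir, manifest, f"phi_fits_atcl{level}.json")).write_text(
            json.dumps(fits, indent=2))
        manifest["stages"][f"phi_atcl{level}"] = {"phi_max": curve.phi_max}

    if summary_rows:
        pd.DataFrame(summary_rows).sort_values("level").to_csv(
            _emit(outdir, manifest, "metrics_summary.csv"), index=False)

    manifest["_stage"] = "strata"
    if records:
        _compare_strata(cfg, records, outdir, manifest)
    manifest.pop("_stage", None)


def _compare_strata(cfg: RunConfig, records, outdir: Path, manifest: dict) -> None:
    groups = strata.stratify(records, cfg.index_date, sex_split=True, age_bins=cfg.age_bins)
    bands = sorted({label.split("_", 1)[1] for label in groups})
    for level in cfg.strata_levels:
        for band in bands:
            f_recs = groups.get(f"F_{band}", [])
            m_recs = groups.get(f"M_{band}", [])
            if not f_recs or not m_recs:
                log.warning("strata %s level %d: empty layer, skipped", band, level)
                continue
            dpn_f = network.build_dpn(ingest.build_incidence(f_recs, level))
            dpn_m = network.build_dpn(ingest.build_incidence(m_recs, level))
            universe = tuple(sorted(set(dpn_f.graph.nodes) | set(dpn_m.graph.nodes)))
            lay_f = strata.binary_layer(dpn_f, universe, label=f"F_{band}")
            lay_m = strata.binary_layer(dpn_m, universe, label=f"M_{band}")
            dist = strata.layer_distance(lay_f, lay_m)
            tag = f"atcl{level}_{band.replace('+', 'plus')}"
            pd.DataFrame(dist.D, index=universe, columns=universe).to_csv(
                _emit(outdir, manifest, f"distance_{tag}.csv"))
            if len(universe) < 3:
                continue
            sym = strata.as_dissimilarity(dist.D)
            link = strata.ward_d2(sym)
            pd.DataFrame(link, columns=["left", "right", "height", "size"]).to_csv(
                _emit(outdir, manifest, f"linkage_{tag}.csv"), index=False)
            if cfg.cluster_k is not None:
                k, sil = cfg.cluster_k, None
            else:
                k, sil = strata.silhouette_k(link, sym)
            clusters = strata.cut_clusters(link, k, labels=universe)
            pd.DataFrame(
                {"code": list(clusters), "cluster": list(clusters.values())}
            ).to_csv(_emit(outdir, manifest, f"clusters_{tag}.csv"), index=False)
            manifest["stages"][f"strata_{tag}"] = {
                "k": int(k), "silhouette": sil, "n_codes": len(universe)}


def _write_manifest(outdir: Path, manifest: dict) -> None:
    manifest.pop("_stage", None)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
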
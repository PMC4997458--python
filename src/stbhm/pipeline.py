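"""End-to-end orchestration: simulate -> preprocess -> fit -> summarize -> trends/exposure.

A single YAML config (plus one global seed) drives every stage; per-stage
seeds are derived by stable hashing so stages are independently reproducible.
Each run writes a manifest recording the config hash, per-stage outputs with
content hashes, the convergence table, and any warnings; identical config and
seed give byte-identical outputs and manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import adjacency as adj_mod
from . import descriptive, geodata, summaries, synthetic
from .model import MCMCConfig, PosteriorDraws, PriorSpec, gelman_rubin, run_mcmc
from .panel import SpaceTimePanel

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES", "save_draws", "load_draws"]

logger = logging.getLogger("stbhm")

ALL_STAGES = ("simulate", "preprocess", "fit", "summarize", "trends", "exposure")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs.

    The synthetic scenario lives in ``truth`` (see
    :class:`stbhm.synthetic.TruthConfig`); ``unit_rows x unit_cols`` units on
    a Queen lattice, each owning a ``cells_per_unit``-square block of raster
    cells. ``missing_rate`` punches holes into the simulated rasters so the
    preprocess stage exercises imputation.
    """

    out_dir: str = "runs/default"
    seed: int = 0
    unit_rows: int = 10
    unit_cols: int = 10
    cells_per_unit: int = 3
    missing_rate: float = 0.02
    population_total: float = 1e8
    truth: synthetic.TruthConfig = field(default_factory=synthetic.TruthConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    grade_breaks: tuple[float, ...] = (15.0, 25.0, 35.0, 70.0)
    exposure_thresholds: tuple[float, ...] = (15.0, 25.0, 35.0, 70.0, 100.0)
    rhat_threshold: float = 1.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "truth" in raw:
            t = dict(raw["truth"])
            for key in ("s_hotspots", "b1_hotspots"):
                if key in t:
                    t[key] = tuple(
                        synthetic.HotspotSpec(
                            center=tuple(h["center"]),
                            radius=h["radius"],
                            amplitude=h["amplitude"],
                            shape=h.get("shape", "gauss"),
                        )
                        for h in t[key]
                    )
            if "years" in t:
                t["years"] = tuple(t["years"])
            raw["truth"] = synthetic.TruthConfig(**t)
        if "priors" in raw:
            raw["priors"] = PriorSpec(**raw["priors"])
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        for key in ("grade_breaks", "exposure_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# draws serialization (columnar CSV per chain)
# ---------------------------------------------------------------------------


def save_draws(draws: PosteriorDraws, out_dir) -> list[Path]:
    """One wide CSV per chain (vector parameters expanded to name_k columns)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(draws.n_chains):
        cols: dict[str, np.ndarray] = {}
        for name in draws.names():
            arr = draws.draws[name][c]
            if arr.ndim == 1:
                cols[name] = arr
            else:
                for k in range(arr.shape[1]):
                    cols[f"{name}_{k + 1}"] = arr[:, k]
        path = out_dir / f"draws_chain{c}.csv"
        pd.DataFrame(cols).to_csv(path, index=False)
        paths.append(path)
    meta = {
        "years": draws.years.tolist(),
        "thin": draws.thin,
        "n_burnin": draws.n_burnin,
        "acceptance": draws.acceptance,
        "n_chains": draws.n_chains,
    }
    meta_path = out_dir / "draws_meta.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    paths.append(meta_path)
    return paths


def load_draws(out_dir) -> PosteriorDraws:
    out_dir = Path(out_dir)
    with open(out_dir / "draws_meta.json", "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    chains = []
    for c in range(meta["n_chains"]):
        chains.append(pd.read_csv(out_dir / f"draws_chain{c}.csv"))
    draws: dict[str, np.ndarray] = {}
    cols = chains[0].columns
    scalar = [c for c in cols if "_" not in c or not c.rsplit("_", 1)[1].isdigit()]
    vector_bases = sorted({c.rsplit("_", 1)[0] for c in cols if c not in scalar})
    for name in scalar:
        draws[name] = np.stack([df[name].to_numpy() for df in chains])
    for base in vector_bases:
        ks = sorted(
            (int(c.rsplit("_", 1)[1]) for c in cols if c.rsplit("_", 1)[0] == base and c not in scalar)
        )
        draws[base] = np.stack(
            [np.column_stack([df[f"{base}_{k}"].to_numpy() for k in ks]) for df in chains]
        )
    return PosteriorDraws(
        draws=draws,
        years=np.array(meta["years"], dtype=int),
        thin=meta["thin"],
        n_burnin=meta["n_burnin"],
        acceptance=meta["acceptance"],
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, manifest: dict) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    adj = adj_mod.queen_lattice(cfg.unit_rows, cfg.unit_cols)
    zones = synthetic.block_zones(cfg.unit_rows, cfg.unit_cols, cfg.cells_per_unit)
    truth = synthetic.make_truth(
        adj, cfg.truth, seed=seed, lattice_shape=(cfg.unit_rows, cfg.unit_cols)
    )
    rng = np.random.default_rng(seed + 1)
    panel = synthetic.simulate_panel(truth, seed=rng)
    rasters = synthetic.simulate_concentration_rasters(
        truth, zones, seed=rng, missing_rate=cfg.missing_rate
    )
    pop = synthetic.simulate_population(
        zones, truth, total=cfg.population_total, seed=rng, noise_sd=0.3
    )
    raster_dir = out / "rasters"
    raster_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for g in rasters:
        p = raster_dir / f"conc_{g.year}.asc"
        geodata.write_raster(g, p)
        outputs.append(p)
    zpath = out / "zones.asc"
    geodata.write_raster(
        geodata.RasterGrid(values=zones.labels.astype(float), nodata_value=-1.0), zpath
    )
    ppath = out / "population.asc"
    geodata.write_raster(pop, ppath)
    panel_path = out / "panel.csv"
    panel.to_csv(panel_path)
    gal_path = out / "neighbors.gal"
    adj_mod.write_neighbor_list(adj, gal_path)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    manifest["stages"]["simulate"] = {
        "seed": seed,
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in outputs + [zpath, ppath, panel_path, gal_path, truth_path]},
    }


def _load_zones(out: Path) -> geodata.ZoneLabels:
    zgrid = geodata.read_raster(out / "zones.asc", nodata=-1.0)
    return geodata.ZoneLabels(labels=zgrid.values.astype(int))


def _load_rasters(out: Path, imputed: bool = True) -> list[geodata.RasterGrid]:
    sub = "rasters_imputed" if imputed else "rasters"
    paths = sorted((out / sub).glob("conc_*.asc"))
    if not paths:
        raise FileNotFoundError(f"no rasters under {out / sub}")
    grids = []
    for p in paths:
        g = geodata.read_raster(p)
        g.year = int(p.stem.split("_")[1])
        grids.append(g)
    return grids


def _stage_preprocess(cfg: RunConfig, out: Path, manifest: dict) -> None:
    zones = _load_zones(out)
    grids = _load_rasters(out, imputed=False)
    imp_dir = out / "rasters_imputed"
    imp_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    imputed = []
    for g in grids:
        filled = geodata.impute_focal(g) if g.n_missing else g
        p = imp_dir / f"conc_{g.year}.asc"
        geodata.write_raster(filled, p)
        imputed.append(filled)
        outputs[str(p.relative_to(out))] = _sha256(p)
    panel = geodata.build_panel(imputed, zones)
    ppath = out / "panel_from_rasters.csv"
    panel.to_csv(ppath)
    outputs[str(ppath.relative_to(out))] = _sha256(ppath)
    manifest["stages"]["preprocess"] = {"outputs": outputs}


def _stage_fit(cfg: RunConfig, out: Path, manifest: dict) -> None:
    panel = SpaceTimePanel.from_csv(out / "panel.csv")
    adj = adj_mod.read_neighbor_list(out / "neighbors.gal")
    mcmc = replace(cfg.mcmc, seed=stage_seed(cfg.seed, "fit"))
    draws = run_mcmc(panel, adj, cfg.priors, mcmc)
    draws_dir = out / "draws"
    paths = save_draws(draws, draws_dir)
    rhat = {
        "alpha": float(gelman_rubin(draws, "alpha")),
        "b0": float(gelman_rubin(draws, "b0")),
        "S_max": float(np.max(gelman_rubin(draws, "S"))),
        "b1_max": float(np.max(gelman_rubin(draws, "b1"))),
    }
    warnings = [
        f"R-hat {k} = {v:.3f} exceeds {cfg.rhat_threshold}"
        for k, v in rhat.items()
        if v > cfg.rhat_threshold
    ]
    runlog = {
        "rhat": rhat,
        "acceptance": draws.acceptance,
        "n_chains": draws.n_chains,
        "n_draws": draws.n_draws,
    }
    runlog_path = out / "fit_runlog.json"
    with open(runlog_path, "w", encoding="utf-8") as fh:
        json.dump(runlog, fh, indent=1, sort_keys=True)
    manifest["stages"]["fit"] = {
        "seed": mcmc.seed,
        "rhat": rhat,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in paths + [runlog_path]},
    }
    manifest["warnings"].extend(warnings)


def _stage_summarize(cfg: RunConfig, out: Path, manifest: dict) -> None:
    draws = load_draws(out / "draws")
    units = summaries.summarize_units(draws)
    units_path = out / "units.csv"
    units.to_csv(units_path, index=False)
    overall = summaries.overall_level_and_trend(draws)
    overall_path = out / "overall.json"
    with open(overall_path, "w", encoding="utf-8") as fh:
        json.dump(overall, fh, indent=1, sort_keys=True)
    manifest["stages"]["summarize"] = {
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in [units_path, overall_path]},
    }


def _stage_trends(cfg: RunConfig, out: Path, manifest: dict) -> None:
    zones = _load_zones(out)
    grids = _load_rasters(out, imputed=True)
    scheme = geodata.GradeScheme(breaks=cfg.grade_breaks)
    mean_series = descriptive.AnnualSeries(
        years=tuple(int(g.year) for g in grids),
        values=tuple(float(g.values[zones.labels > 0].mean()) for g in grids),
    )
    q90_series = descriptive.quantile_series(grids, 0.9, zones)
    fits = {
        "mean": descriptive.ols_trend(mean_series),
        "q90": descriptive.ols_trend(q90_series),
    }
    grade_series = descriptive.grade_area_series(grids, scheme, zones)
    series_rows = []
    for name, s in [("mean", mean_series), ("q90", q90_series)] + [
        (f"grade{g}_area", s) for g, s in grade_series.items()
    ]:
        for y, v in zip(s.years, s.values):
            series_rows.append({"series": name, "year": y, "value": v})
        if name.startswith("grade"):
            fits[name] = descriptive.ols_trend(s)
    series_path = out / "series.csv"
    pd.DataFrame(series_rows).to_csv(series_path, index=False)
    fit_rows = [
        {
            "series_name": name,
            "slope": f.slope,
            "ci_low": f.ci_low,
            "ci_high": f.ci_high,
            "r_squared": f.r_squared,
        }
        for name, f in fits.items()
    ]
    fits_path = out / "trend_fits.csv"
    pd.DataFrame(fit_rows).to_csv(fits_path, index=False)
    manifest["stages"]["trends"] = {
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in [series_path, fits_path]},
    }


def _stage_exposure(cfg: RunConfig, out: Path, manifest: dict) -> None:
    pop = geodata.read_raster(out / "population.asc")
    grids = _load_rasters(out, imputed=True)
    rows = []
    for g in (grids[0], grids[-1]):
        table = descriptive.exposure_percent(g, pop, cfg.exposure_thresholds)
        for thr, pct in table.items():
            rows.append({"year": int(g.year), "threshold": thr, "percent": pct})
    path = out / "exposure.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    manifest["stages"]["exposure"] = {
        "outputs": {str(path.relative_to(out)): _sha256(path)},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "fit": _stage_fit,
    "summarize": _stage_summarize,
    "trends": _stage_trends,
    "exposure": _stage_exposure,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained. The manifest (also written to
    ``<out_dir>/manifest.json``) is a pure function of config and seed.
    """
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in ALL_STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out, manifest)
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
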
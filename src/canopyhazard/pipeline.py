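"""End-to-end orchestration: simulate/load → filter → rates → modes →
records → survival fits, with a machine-readable manifest.

Every stage's outputs are written under the configured output directory;
the manifest records seeds, thresholds, exclusion counts and per-stage
status, and together with the package version suffices to reproduce a run
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .census import CensusDataset, filter_plots, merge_nearby_plots, read_census_table
from .covariates import assemble_survival_records
from .hazard import ModelSpec, fit_by_mode, fit_cox, model_ladder, stepwise_aic, table1_specs, vif
from .modes import fit_cil_correction, fit_regional_mode_model, plot_mode_proportions
from .rates import bootstrap_weighted_mean, compare_regions, plot_rates_table
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("canopyhazard")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Full-analysis configuration; thresholds default to the standard values
    (10 yr max gap, 0.5 ha min area, 50 %/5 mode eligibility, 3-census
    survival minimum, B = 10,000 bootstrap replicates)."""

    out_dir: str = "canopyhazard_run"
    census_csv: str | None = None
    plots_csv: str | None = None
    traits_csv: str | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    max_census_gap_yr: float = 10.0
    min_area_ha: float = 0.5
    max_elevation_m: float = 1000.0
    merge_km: float = 1.0
    min_censuses_survival: int = 3
    bootstrap_B: int = 10_000
    frailty: bool = True
    run_stepwise: bool = True
    run_mode_fits: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    Any stage failure is recorded in the manifest and later stages that can
    still run, run; outputs produced before a failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "max_census_gap_yr": cfg.max_census_gap_yr,
            "min_area_ha": cfg.min_area_ha,
            "max_elevation_m": cfg.max_elevation_m,
            "merge_km": cfg.merge_km,
            "min_censuses_survival": cfg.min_censuses_survival,
            "bootstrap_B": cfg.bootstrap_B,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = _time.time()
            try:
                result = fn()
                manifest["stages"][name] = {"status": "ok", "seconds": round(_time.time() - t0, 2)}
                return result
            except Exception as exc:
                log.exception("stage %s failed", name)
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                return None
        return deco

    # --- input -----------------------------------------------------------
    @stage("input")
    def ds() -> CensusDataset:
        if cfg.simulation is not None:
            sim_cfg = cfg.simulation.replace(seed=cfg.seed)
            d, truth = simulate_dataset(sim_cfg)
            truth.trees.to_csv(out / "truth_trees.csv", index=False)
            manifest["simulation"] = dataclasses.asdict(sim_cfg)
            return d
        if not cfg.census_csv or not cfg.plots_csv:
            raise ValueError("need either a simulation config or census+plot CSV paths")
        return read_census_table(cfg.census_csv, cfg.plots_csv, cfg.traits_csv)

    if ds is None:
        _write_manifest(out, manifest)
        raise RuntimeError("input stage failed; see manifest")

    # --- filtering -------------------------------------------------------
    @stage("filter")
    def filtered():
        merged, merge_report = merge_nearby_plots(ds, max_distance_km=cfg.merge_km)
        kept, report = filter_plots(
            merged,
            max_census_gap_yr=cfg.max_census_gap_yr,
            min_area_ha=cfg.min_area_ha,
            max_elevation_m=cfg.max_elevation_m,
            min_censuses=2,
        )
        report.to_csv(out / "plot_exclusions.csv", index=False)
        manifest["stages"]["filter"] = {
            "status": "ok",
            "plots_in": len(ds.plots),
            "plots_kept": len(kept.plots),
            "unmerged_incompatible": len(merge_report),
        }
        return kept

    work = filtered if filtered is not None else ds

    # --- rates -----------------------------------------------------------
    @stage("rates")
    def rates_tables():
        plot_rates = plot_rates_table(work)
        plot_rates.to_csv(out / "plot_rates.csv", index=False)
        summaries = []
        s = bootstrap_weighted_mean(
            plot_rates["m_plot"], plot_rates["area_ha"], B=cfg.bootstrap_B,
            seed=cfg.seed, scope="basin",
        )
        summaries.append(dataclasses.asdict(s))
        for region, sub in plot_rates.groupby("region"):
            if len(sub) >= 2:
                s = bootstrap_weighted_mean(
                    sub["m_plot"], sub["area_ha"], B=cfg.bootstrap_B,
                    seed=cfg.seed + 1, scope=region,
                )
                summaries.append(dataclasses.asdict(s))
        pd.DataFrame(summaries).to_csv(out / "rate_summaries.csv", index=False)
        if plot_rates["region"].nunique() >= 2:
            tukey = compare_regions(plot_rates)
            tukey.to_csv(out / "region_tukey.csv", index=False)
            manifest["region_letters"] = tukey.attrs["letters"]
        for mode in ("standing", "broken_uprooted"):
            mt = plot_rates_table(work, mode=mode)
            mt.to_csv(out / f"plot_rates_{mode}.csv", index=False)
        return plot_rates

    # --- mode of death ---------------------------------------------------
    @stage("modes")
    def mode_tables():
        props = plot_mode_proportions(work)
        props.to_csv(out / "mode_proportions.csv", index=False)
        results = {}
        if len(props) >= 6:
            for mode in ("standing", "broken_uprooted"):
                corr = fit_cil_correction(props, mode=mode)
                results[mode] = dataclasses.asdict(corr)
                if props["region"].nunique() >= 2:
                    est, contrasts = fit_regional_mode_model(props, mode=mode)
                    pd.DataFrame([dataclasses.asdict(e) for e in est]).to_csv(
                        out / f"mode_regional_{mode}.csv", index=False
                    )
                    contrasts.to_csv(out / f"mode_contrasts_{mode}.csv", index=False)
            with open(out / "mode_corrections.json", "w") as fh:
                json.dump(results, fh, indent=2, default=_jsonable)
        return props

    # --- survival records ------------------------------------------------
    @stage("records")
    def records():
        recs, report = assemble_survival_records(
            work, min_censuses=cfg.min_censuses_survival
        )
        recs.to_csv(out / "survival_records.csv", index=False)
        report.excluded.to_csv(out / "record_exclusions.csv", index=False)
        manifest["record_exclusion_counts"] = {k: int(v) for k, v in report.counts.items()}
        return recs

    # --- survival fits ---------------------------------------------------
    if records is not None and len(records) and records["event"].sum() > 0:
        @stage("survival")
        def fits():
            full = ModelSpec(frailty=cfg.frailty, description="Full model")
            v = vif(records, full.terms)
            v.to_csv(out / "vif.csv")
            ladder = model_ladder(records, table1_specs(frailty=cfg.frailty))
            ladder.to_csv(out / "model_ladder.csv", index=False)
            result = {"ladder_best": ladder.iloc[0]["description"],
                      "vif_max": float(v.max())}
            fit = fit_cox(records, full)
            result["full_model"] = {
                "terms": list(fit.terms),
                "coef": fit.coef.tolist(),
                "se": fit.se.tolist(),
                "chi2": fit.chi2.tolist(),
                "loglik": fit.loglik,
                "aic": fit.aic,
                "theta": fit.theta,
                "n": fit.n,
                "n_events": fit.n_events,
            }
            if cfg.run_stepwise:
                selected, trace = stepwise_aic(records, full, refit_frailty=False)
                trace.to_csv(out / "stepwise_trace.csv", index=False)
                result["stepwise_selected"] = list(selected.terms)
            if cfg.run_mode_fits:
                by_mode = fit_by_mode(records, full)
                result["by_mode"] = {
                    m: (f if isinstance(f, str) else {
                        "coef": f.coef.tolist(), "se": f.se.tolist(),
                        "n_events": f.n_events,
                    })
                    for m, f in by_mode.items()
                }
            with open(out / "survival_fits.json", "w") as fh:
                json.dump(result, fh, indent=2, default=_jsonable)
            return result

        manifest["survival"] = fits if isinstance(fits, dict) else None

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
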
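"""End-to-end orchestration of the serum-zinc analysis.

Stage order: simulate (or read) -> exclusion cascade -> inflammation
staging -> BRINDA fit and adjustment -> deficiency classification and
weighted prevalence -> demographic summaries -> EA aggregation (mapping
group only) -> Tukey screening -> variogram estimation for each estimator
-> WLS exponential fits -> SSPE-based model selection -> grid kriging ->
exceedance-probability map.  Every stage writes its output under the run
directory and the manifest records counts, parameters and the chosen
model, so a rerun with the same config and seed reproduces the numbers
exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brinda, geostats, kriging, prevalence, survey, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("zincgeo")


@dataclass
class PipelineConfig:
    """One config object (and YAML schema) for the whole run."""

    output_dir: str
    seed: int
    input_csv: str | None = None            # if None, simulate
    simulation: dict = field(default_factory=dict)
    cutoff_csv: str | None = None
    mapping_group: str = "WRA"
    deficiency_threshold: float = 70.0      # ug/dL, exceedance map
    lag_bin_width_km: float = 10.0
    max_lag_km: float = 200.0
    estimators: tuple[str, ...] = ("matheron", "cressie_hawkins", "dowd")
    grid_resolution_deg: float = 0.25
    grid_node_cap: int = 1_000_000

    def __post_init__(self) -> None:
        if self.deficiency_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input file not found: {self.input_csv}")
        if self.cutoff_csv is not None and not Path(self.cutoff_csv).exists():
            raise ValueError(f"cutoff file not found: {self.cutoff_csv}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "estimators" in raw:
            raw["estimators"] = tuple(raw["estimators"])
        return cls(**raw)


def _stage(name: str, n: int | None = None) -> None:
    log.info("stage=%s%s", name, f" n={n}" if n is not None else "")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed}

    # --- input ------------------------------------------------------------
    if config.input_csv is None:
        sim_cfg = synthetic.SimulationConfig(seed=config.seed, **config.simulation)
        df, truth = synthetic.simulate_survey(sim_cfg)
        synthetic.write_survey(df, out / "survey.csv")
        synthetic.write_ground_truth(truth, out / "ground_truth.json")
        df = survey.read_survey(out / "survey.csv")  # same path users take
        manifest["input"] = "simulated"
    else:
        df = survey.read_survey(config.input_csv)
        manifest["input"] = str(config.input_csv)
    manifest["n_input"] = len(df)
    _stage("input", len(df))

    # --- exclusions and staging -------------------------------------------
    retained, report = survey.apply_exclusions(df)
    report.to_json(out / "exclusion_report.json")
    manifest["exclusions"] = report.counts
    manifest["n_retained"] = report.n_retained
    _stage("exclusions", report.n_retained)

    retained = survey.stage_inflammation_frame(retained)

    # --- BRINDA -------------------------------------------------------------
    fit = brinda.fit_brinda(retained)
    fit.to_json(out / "brinda_fit.json")
    working = brinda.adjust_frame(retained, fit)
    working.to_csv(out / "working_table.csv", index=False)
    manifest["brinda"] = {
        "beta1": fit.beta1, "beta2": fit.beta2,
        "ref_lncrp": fit.ref_lncrp, "ref_lnagp": fit.ref_lnagp,
        "n_fit": fit.n_fit,
    }
    _stage("brinda", fit.n_fit)

    # --- prevalence and summaries ------------------------------------------
    cutoffs = (
        prevalence.CutoffTable.from_csv(config.cutoff_csv)
        if config.cutoff_csv else prevalence.load_default_cutoffs()
    )
    prev_group = prevalence.estimate_prevalence(working, "group", cutoffs=cutoffs)
    prev_region = prevalence.estimate_prevalence(working, "region", cutoffs=cutoffs)
    prev_group.to_csv(out / "prevalence_by_group.csv", index=False)
    prev_region.to_csv(out / "prevalence_by_region.csv", index=False)
    national = prev_group[prev_group["stratum"] == "National"].iloc[0]
    manifest["prevalence_national"] = {
        "unadjusted": float(national["prevalence_unadjusted"]),
        "adjusted": float(national["prevalence_adjusted"]),
    }
    for by in ("region", "group", "residence", "stage"):
        tab = survey.weighted_summary(working, by, value_cols=("zn", "zn_adjusted"))
        tab.to_csv(out / f"summary_by_{by}.csv", index=False)
    _stage("prevalence")

    # --- spatial analysis ----------------------------------------------------
    mapping = working[working["group"] == config.mapping_group]
    if mapping.empty:
        raise RuntimeError(
            f"stage=aggregate: no records in mapping group {config.mapping_group!r}"
        )
    agg = geostats.aggregate_by_ea(mapping, value_col="zn_adjusted")
    agg.to_csv(out / "ea_aggregates.csv", index=False)
    manifest["n_ea_aggregates"] = len(agg)
    _stage("aggregate", len(agg))

    mask, fences = geostats.tukey_outliers(agg["mean_zn"].to_numpy())
    screened = agg[~mask].reset_index(drop=True)
    manifest["variogram_outliers_withheld"] = int(mask.sum())
    manifest["tukey_fences"] = list(fences)

    bins = geostats.make_lag_bins(config.lag_bin_width_km, config.max_lag_km)
    fits: dict[str, geostats.VariogramModel] = {}
    for est in config.estimators:
        vg = geostats.estimate_variogram(screened, bins, estimator=est)
        vg.bins.to_csv(out / f"variogram_{est}.csv", index=False)
        fits[est] = geostats.fit_exponential_wls(vg)
    _stage("variogram", len(fits))

    selection = kriging.select_model(fits, screened)
    selection.to_json(out / "model_selection.json")
    model = selection.model
    manifest["variogram_model"] = {
        "estimator": selection.chosen_estimator,
        "c0": model.c0, "c1": model.c1, "a": model.a,
        "effective_range_km": model.effective_range,
        "spatially_dependent_fraction": model.spatially_dependent_fraction,
        "median_sspe": selection.median_sspe,
        "is_valid": selection.is_valid,
    }
    cv = kriging.cross_validate(screened, model)
    cv.to_frame().to_csv(out / "cross_validation_errors.csv", index=False)
    _stage("select", None)

    # outliers reinstated for prediction
    lon_rng = (float(agg["mean_lon"].min()), float(agg["mean_lon"].max()))
    lat_rng = (float(agg["mean_lat"].min()), float(agg["mean_lat"].max()))
    grid = kriging.predict_grid(
        agg, model, lon_rng, lat_rng,
        resolution_deg=config.grid_resolution_deg, node_cap=config.grid_node_cap,
    )
    probs = kriging.exceedance_probability(
        grid["prediction"], grid["variance"], config.deficiency_threshold
    )
    grid = pd.concat([grid, probs], axis=1)
    grid.to_csv(out / "prediction_grid.csv", index=False)
    manifest["grid"] = {
        "n_nodes": len(grid),
        "resolution_deg": config.grid_resolution_deg,
        "threshold": config.deficiency_threshold,
        "mean_prediction": float(grid["prediction"].mean()),
        "mean_variance": float(grid["variance"].mean()),
        "share_p_below_gt_0.66": float((grid["p_below"] > 0.66).mean()),
    }
    _stage("grid", len(grid))

    Path(out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
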
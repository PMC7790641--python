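"""End-to-end pipeline: simulate → calibrate → estimate → evaluate → paleo.

Each stage reads its inputs from and writes its outputs to one run
directory, so the staged CLI subcommands and :func:`run_pipeline` are the
same code path.  Every JSON output carries the config hash and seed; a run
is deterministic given both.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import communities, estimators, evaluation, io, paleo, synthetic
from .config import RunConfig
from .errors import ValidationError

METHOD_COLUMNS = ("linear", "polynomial", "knn", "mlgrid")


def _metadata(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed,
            "config": config.to_dict()}


def stage_simulate(config: RunConfig, run_dir: str | Path) -> Path:
    """Generate a synthetic landscape and fossil sites; write input CSVs."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    landscape = synthetic.generate_landscape(config.landscape_config())
    io.write_landscape(landscape, run_dir)
    sites, gcms = synthetic.generate_fossil_sites(
        landscape,
        n_sites=config.n_fossil_sites,
        n_glacial=config.n_glacial,
        species_per_site=config.species_per_site,
        include_out_of_space=config.include_out_of_space,
        n_out_of_space=config.n_out_of_space,
        seed=config.seed,
    )
    io.write_fossil_sites(sites, run_dir / "fossil_sites.csv")
    io.write_gcm(gcms, run_dir / "gcm.csv")
    io.write_json(_metadata(config), run_dir / "run_manifest.json")
    return run_dir


def stage_calibrate(config: RunConfig, run_dir: str | Path) -> communities.CalibrationSet:
    """Score communities, apply the richness floor, pair with log precip."""
    run_dir = Path(run_dir)
    traits = io.read_traits(run_dir / "traits.csv")
    points, lists = io.read_communities(run_dir / "communities.csv")
    env = io.read_environment(run_dir / "environment.csv")
    metrics, report = communities.community_metrics(
        lists, traits, min_richness=config.min_richness
    )
    cal = communities.build_calibration(metrics, env)
    table = cal.records.merge(points, on="point_id", how="left")
    table = table[["point_id", "x", "y", "mean", "sd", "richness", "env_log"]]
    io.write_calibration_table(table, run_dir / "calibration.csv")
    io.write_json(
        {**report.to_dict(), **_metadata(config)}, run_dir / "filter_report.json"
    )
    return cal


def _load_calibration(run_dir: Path) -> tuple[communities.CalibrationSet, pd.DataFrame]:
    table = io.read_calibration_table(run_dir / "calibration.csv")
    cal = communities.CalibrationSet(
        records=table[["point_id", "mean", "sd", "richness", "env_log"]].copy()
    )
    return cal, table


def stage_estimate(
    config: RunConfig, run_dir: str | Path, methods: tuple[str, ...] = METHOD_COLUMNS
) -> estimators.ModelSet:
    """Fit the four estimators on the calibration set; predict every point."""
    run_dir = Path(run_dir)
    cal, table = _load_calibration(run_dir)
    models = estimators.fit_all(
        cal,
        k=config.knn_k,
        training_fraction=config.knn_training_fraction,
        distance_space=config.knn_distance_space,
        n_bins=config.ml_bins,
        bin_estimate=config.ml_bin_estimate,
        seed=config.seed,
    )
    io.save_models(models, run_dir / "models.json", metadata=_metadata(config))
    est = pd.DataFrame({"point_id": table["point_id"], "observed_log": table["env_log"]})
    means, sds = cal.means, cal.sds
    if "linear" in methods:
        est["linear"] = estimators.predict_linear(models.linear, means)
    if "polynomial" in methods:
        est["polynomial"] = estimators.predict_polynomial(models.polynomial, means)
    if "knn" in methods:
        est["knn"] = estimators.predict_knn(
            models.knn, means, sds if config.knn_distance_space == "mean_sd" else None
        )
    if "mlgrid" in methods:
        est["mlgrid"] = estimators.predict_mlgrid(models.mlgrid, means, sds)
    est.to_csv(run_dir / "estimates.csv", index=False)
    return models


def stage_evaluate(config: RunConfig, run_dir: str | Path) -> evaluation.ComparisonReport:
    """Anomaly fields, correlation matrix and ANOVA on the modern data."""
    run_dir = Path(run_dir)
    _, table = _load_calibration(run_dir)
    est = pd.read_csv(run_dir / "estimates.csv")
    est["point_id"] = est["point_id"].astype(str)
    est = est.set_index("point_id")
    observed = est["observed_log"]
    method_cols = [c for c in METHOD_COLUMNS if c in est.columns]
    if not method_cols:
        raise ValidationError("estimates.csv contains no method columns")
    series = {m: est[m] for m in method_cols}
    if config.knn_holdout_only and "knn" in series:
        models = io.load_models(run_dir / "models.json")
        series["knn"] = series["knn"].drop(
            index=[p for p in models.knn.train_point_ids if p in series["knn"].index]
        )
    fields, report = evaluation.compare_methods(
        observed, series, direction=config.anomaly_direction_modern
    )
    xy = table.set_index("point_id")[["x", "y"]]
    for f in fields:
        out = pd.DataFrame(
            {
                "point_id": f.values.index,
                "x": xy.reindex(f.values.index)["x"].to_numpy(),
                "y": xy.reindex(f.values.index)["y"].to_numpy(),
                "observed_log": observed.reindex(f.values.index).to_numpy(),
                "estimated_log": est[f.method].reindex(f.values.index).to_numpy(),
                "anomaly_log": f.values.to_numpy(),
            }
        )
        out.to_csv(run_dir / f"anomalies_{f.method}.csv", index=False)
    io.write_json({**report.to_dict(), **_metadata(config)}, run_dir / "report.json")
    return report


def stage_paleo(config: RunConfig, run_dir: str | Path) -> pd.DataFrame:
    """Estimate paleoprecipitation at fossil sites and compare with GCMs."""
    run_dir = Path(run_dir)
    sites = io.read_fossil_sites(run_dir / "fossil_sites.csv")
    gcms = io.read_gcm(run_dir / "gcm.csv")
    models = io.load_models(run_dir / "models.json")
    estimates, coverage = paleo.estimate_paleo(sites, models)
    estimates.to_csv(run_dir / "paleo_estimates.csv", index=False)
    anomalies, summary = paleo.compare_to_gcm(
        estimates, gcms, age_match=config.age_match, gcm_average=config.gcm_average
    )
    anomalies.to_csv(run_dir / "paleo_anomalies.csv", index=False)
    io.write_json(
        {
            "ml_coverage": coverage,
            "age_match": config.age_match,
            "summary": summary.replace({np.nan: None}).to_dict(orient="records"),
            **_metadata(config),
        },
        run_dir / "paleo_report.json",
    )
    return anomalies


def run_pipeline(config: RunConfig, run_dir: str | Path) -> Path:
    """Run every stage into ``run_dir``; deterministic given config + seed."""
    config.validate()
    run_dir = Path(run_dir)
    stage_simulate(config, run_dir)
    stage_calibrate(config, run_dir)
    stage_estimate(config, run_dir)
    stage_evaluate(config, run_dir)
    stage_paleo(config, run_dir)
    return run_dir
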
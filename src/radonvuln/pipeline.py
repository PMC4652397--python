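"""End-to-end pipeline driver.

Stages run in the study's order — simulate (optional) -> label -> train (one
balanced forest per threshold) -> metrics & spatial diagnostics -> map ->
trends — and every artifact is written as a documented table.  A JSON
manifest records the effective configuration and the SHA-256 of every file,
so a rerun with the same seed is verifiably identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import PipelineConfig, ForestConfig, substream
from .forest import ForestResults, VulnerabilityForest, covariate_columns
from .mapping import apportion_units, build_threshold_maps, summarize_regions
from .metrics import geary_c, kappa_gain, knn_weights, metric_report
from .synthetic import generate_study
from .trends import (
    HIGHER,
    LOWER,
    annual_ratio_series,
    assign_strata,
    filter_deaths,
    loess_smooth,
    median_smoking_split,
    stratum_summary_table,
)
from .vulnerability import HIGH, LOW, build_training_set, label_column

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "train_threshold_model", "threshold_seed", "plot_trend_grid"]


def threshold_seed(root_seed: int, index: int) -> int:
    """Deterministic per-threshold forest seed derived from the root seed."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(5, index))
    return int(ss.generate_state(1)[0] % (2**31))


def train_threshold_model(
    units: pd.DataFrame,
    labels: pd.DataFrame,
    threshold: float,
    forest_config: ForestConfig,
) -> ForestResults:
    """Fit the balanced forest for one threshold's labels."""
    merged = labels.merge(units, on="unit_id", how="left", validate="one_to_one")
    X = merged[covariate_columns(units)]
    y = merged[label_column(threshold)]
    return VulnerabilityForest(X, y, config=forest_config).fit()


def _series_with_smoothing(stratified, t, years, loess_cfg, **strata):
    frames = []
    for cls in (HIGH, LOW):
        s = annual_ratio_series(stratified, t, cls, years=years, **strata)
        if s["ratio"].notna().sum() >= loess_cfg.degree + 2:
            s["smoothed"] = loess_smooth(
                s["year"], s["ratio"], span=loess_cfg.span, degree=loess_cfg.degree
            )
        else:
            s["smoothed"] = np.nan
        s.insert(0, "vulnerability", cls)
        for k, v in strata.items():
            s.insert(1, k, v)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    write_geojson: bool = False,
    save_models: bool = False,
    n_permutations: int = 199,
) -> dict:
    """Run simulate -> label -> train -> metrics -> map -> trends; return manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    files: list[Path] = []
    stage_log: dict[str, dict] = {}

    def _stage(name, **info):
        stage_log[name] = {"elapsed_s": round(time.time() - t0, 2), **info}
        logger.info("stage %s done: %s", name, info)

    # -- simulate ----------------------------------------------------------
    gen = config.generator
    if gen.seed != config.seed:
        gen = type(gen)(**{**gen.to_dict(), "seed": config.seed})
    study = generate_study(gen)
    files.append(rio.write_table(study.units, out / "units.csv", "units"))
    files.append(rio.write_table(study.measurements, out / "measurements.csv", "measurements"))
    files.append(rio.write_table(study.deaths, out / "deaths.csv", "deaths"))
    files.append(rio.write_table(study.health_areas, out / "health_areas.csv", "health_areas"))
    files.append(rio.write_table(study.truth, out / "truth.csv", "truth"))
    if write_geojson:
        files.append(rio.write_units_geojson(study.units, out / "units.geojson"))
    _stage("simulate", n_units=len(study.units), n_measurements=len(study.measurements),
           n_deaths=len(study.deaths))

    # -- label -------------------------------------------------------------
    labels, distribution = build_training_set(study.units, study.measurements, config.ladder)
    files.append(rio.write_table(labels, out / "labels.csv", "labels"))
    distribution.to_csv(out / "class_distribution.csv", index=False)
    files.append(out / "class_distribution.csv")
    _stage("label", n_training_units=len(labels))

    # -- train + metrics ---------------------------------------------------
    results: dict[float, ForestResults] = {}
    rows = []
    for i, t in enumerate(sorted(config.ladder)):
        fc = ForestConfig(
            n_runs=config.forest.n_runs,
            n_trees_per_run=config.forest.n_trees_per_run,
            n_features_per_split=config.forest.n_features_per_split,
            min_leaf_size=config.forest.min_leaf_size,
            seed=threshold_seed(config.seed, i),
        )
        res = train_threshold_model(study.units, labels, t, fc)
        results[t] = res
        rows.append({"threshold": t, **metric_report(res.confusion_matrix)})
        if save_models:
            p = out / f"model_T{t:g}.json"
            res.to_json(p)
            files.append(p)
    report = pd.DataFrame(rows)
    gains = kappa_gain(dict(zip(report["threshold"], report["kappa"])))
    report["kappa_gain"] = report["threshold"].map(gains)
    report = report.sort_values("threshold", ascending=False, ignore_index=True)
    files.append(rio.write_table(report, out / "report.csv", "report"))
    _stage("train", n_models=len(results))

    # -- spatial diagnostics ----------------------------------------------
    coords = labels.merge(study.units[["unit_id", "x", "y"]], on="unit_id")
    w = knn_weights(coords[["x", "y"]].to_numpy(), k=8)
    c_val, p_val = geary_c(
        coords["p95"].to_numpy(), w, n_permutations=n_permutations, seed=config.seed
    )
    diag = {"geary_c_p95": c_val, "geary_p_value": p_val, "n_permutations": n_permutations}
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    files.append(out / "diagnostics.json")
    _stage("diagnostics", **diag)

    # -- map ---------------------------------------------------------------
    maps = build_threshold_maps(results, study.units)
    for t in sorted(config.ladder):
        p = out / f"map_T{t:g}.csv"
        rio.write_table(maps[["unit_id", label_column(t)]], p, "map")
        files.append(p)
    populations = apportion_units(study.units)
    summaries = summarize_regions(maps, study.units, populations)
    files.append(rio.write_table(summaries, out / "regional_summary.csv", "regional_summary"))
    _stage("map", n_regions=summaries["region_id"].nunique())

    # -- trends ------------------------------------------------------------
    natural, drop_log = filter_deaths(study.deaths)
    smoking = median_smoking_split(
        study.health_areas.set_index("health_area_id")["smoking_prevalence"]
    )
    stratified, exclusions = assign_strata(natural, maps, smoking)
    years = list(range(gen.first_year, gen.first_year + gen.n_years))
    for t in sorted(config.ladder):
        total = _series_with_smoothing(stratified, t, years, config.loess)
        smoke = pd.concat(
            [
                _series_with_smoothing(stratified, t, years, config.loess, smoking=s)
                for s in (HIGHER, LOWER)
            ],
            ignore_index=True,
        )
        sex = pd.concat(
            [
                _series_with_smoothing(stratified, t, years, config.loess, sex=s)
                for s in ("male", "female")
            ],
            ignore_index=True,
        )
        for name, frame in (("total", total), ("smoking", smoke), ("sex", sex)):
            p = out / f"trends_T{t:g}_{name}.csv"
            frame.to_csv(p, index=False, float_format=rio.FLOAT_FORMAT)
            files.append(p)
    summary = stratum_summary_table(stratified, config.ladder)
    files.append(rio.write_table(summary, out / "stratum_summary.csv", "stratum_summary"))
    _stage("trends", **drop_log, ineligible_deaths=exclusions)

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "stages": stage_log,
        "files": {p.name: rio.file_sha256(p) for p in sorted(set(files))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def plot_trend_grid(stratified, ladder, loess_cfg, path, row_strata=None) -> None:
    """Panel grid of crude-ratio trends: columns are thresholds, rows strata.

    ``row_strata`` maps row title -> kwargs for the series selection (e.g.
    {"total": {}, "higher smoking": {"smoking": "higher"}}).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if row_strata is None:
        row_strata = {"total": {}, "higher smoking": {"smoking": HIGHER},
                      "lower smoking": {"smoking": LOWER}}
    thresholds = sorted(ladder)
    fig, axes = plt.subplots(
        len(row_strata), len(thresholds),
        figsize=(2.2 * len(thresholds), 2.2 * len(row_strata)),
        sharex=True, sharey="row", squeeze=False,
    )
    for j, t in enumerate(thresholds):
        for i, (title, kw) in enumerate(row_strata.items()):
            ax = axes[i][j]
            frame = _series_with_smoothing(stratified, t, None, loess_cfg, **kw)
            for cls, color in ((HIGH, "firebrick"), (LOW, "seagreen")):
                s = frame[frame["vulnerability"] == cls]
                ax.plot(s["year"], s["ratio"], ".", ms=3, color=color, alpha=0.5)
                ax.plot(s["year"], s["smoothed"], "-", color=color, label=cls)
            if i == 0:
                ax.set_title(f"{t:g} Bq m$^{{-3}}$", fontsize=9)
            if j == 0:
                ax.set_ylabel(title, fontsize=9)
    axes[0][0].legend(fontsize=7)
    fig.suptitle("Crude lung cancer mortality ratio by radon vulnerability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
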
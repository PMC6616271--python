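"""End-to-end analysis orchestration: weather -> signals -> features ->
hysteresis -> fitted models -> water-deficit threshold.

``run_pipeline`` executes the stages in order on either a synthetic scenario
or on-disk CSVs, writes the analysis tables (features, loop metrics,
correlations, fitted models, threshold) plus a provenance log, and returns a
run report.  Re-running with the same configuration and seed reproduces all
numeric outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ValidationError
from .features import compute_window_features
from .hysteresis import build_loop, loop_metrics_table
from .models import correlate, fit_expolinear, fit_multilinear_psistem
from .signals import (
    average_rates,
    average_standardized,
    compute_rgr,
    compute_rpcr,
    qc_filter,
    smooth_series,
    standardize,
)
from .synth import ExperimentBundle, ScenarioConfig, gen_experiment, tree_week_means

log = logging.getLogger("dielsense")


@dataclass
class PipelineConfig:
    """What to analyse and where to write it."""

    out_dir: str = "dielsense_out"
    seed: int = 0
    scenario: ScenarioConfig | None = None  # synthetic mode when set
    sensors_dir: str | None = None  # ingestion mode (unused in synthetic mode)
    weather_csv: str | None = None
    spots_csv: str | None = None
    feature_pairs_csv: str | None = None
    smoothing_window: int = 15
    smoothing_degree: int = 3
    max_excluded_fraction: float = 0.05
    completeness_min: float = 0.8
    threshold_fraction: float = 0.01
    treatments: tuple[str, ...] | None = None  # subset filter
    stages: tuple[str, ...] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scenario is not None:
            cfg.scenario = ScenarioConfig(**scenario)
        return cfg


@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    status: str
    out_dir: str
    n_series: int = 0
    threshold: float | None = None
    expolinear_params: dict = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _load_bundle(config: PipelineConfig) -> ExperimentBundle:
    if config.scenario is not None:
        scenario = config.scenario
        if scenario.seed != config.seed:
            scenario = ScenarioConfig(**{**scenario.__dict__, "seed": config.seed})
        return gen_experiment(scenario)
    raise ValidationError("on-disk ingestion requires sensors_dir/weather_csv; use a scenario or the CLI ingest path")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis and write its outputs under ``config.out_dir``.

    Stage order: simulate/ingest, QC + smoothing, standardisation and rate
    transforms (per tree, averaging sensors), per-window features and
    fruit/leaf ratios, hysteresis loop metrics, spot-sensor correlations, the
    multilinear stem-water-potential fit, the expo-linear calibration fit and
    its water-deficit threshold.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(status="success", out_dir=str(out))

    bundle = _load_bundle(config)
    spots = bundle.spots

    # ---- per tree-stage: QC, smooth, average sensors, rates, features, loops
    features_rows, loops, corr_pairs = [], [], {"fruit_z": [], "leaf_z": [], "psi_stem": [], "psi_leaf": []}
    keys = sorted({(t, tr, s) for (t, tr, s, _, _) in bundle.sensors})
    for treatment, tree_id, stage_id in keys:
        if config.treatments and treatment not in config.treatments:
            continue
        if config.stages and stage_id not in config.stages:
            continue
        try:
            organs = {}
            for organ in ("fruit", "leaf"):
                cleaned = []
                sensor_ids = sorted(
                    s for (t, tr, st, o, s) in bundle.sensors if (t, tr, st, o) == (treatment, tree_id, stage_id, organ)
                )
                for sensor in sensor_ids:
                    series = bundle.sensors[(treatment, tree_id, stage_id, organ, sensor)]
                    series = qc_filter(series, config.max_excluded_fraction)
                    series = smooth_series(series, config.smoothing_window, config.smoothing_degree)
                    cleaned.append(series)
                organs[organ] = cleaned
            rgr = average_rates([compute_rgr(s) for s in organs["fruit"]])
            rpcr = average_rates([compute_rpcr(s) for s in organs["leaf"]])
            fruit_z = average_standardized([standardize(s) for s in organs["fruit"]])
            leaf_z = average_standardized([standardize(s) for s in organs["leaf"]])

            labels = {"treatment": treatment, "tree_id": tree_id, "stage_id": stage_id}
            for kind, rate in (("RGR", rgr), ("RPCR", rpcr)):
                wf = compute_window_features(rate.values, config.completeness_min)
                wf.insert(0, "variable", kind)
                for k, v in labels.items():
                    wf[k] = v
                features_rows.append(wf)
            for day in sorted({ts.normalize() for ts in rgr.values.index}):
                loop = build_loop(rgr, rpcr, day)
                if loop.n_points:
                    loops.append((dict(labels), loop))

            spot_sel = spots[(spots["tree_id"] == tree_id) & (spots["stage_id"] == stage_id)]
            for _, row in spot_sel.iterrows():
                ts = row["timestamp"]
                if ts in fruit_z.index and ts in leaf_z.index:
                    corr_pairs["fruit_z"].append(float(fruit_z.loc[ts]))
                    corr_pairs["leaf_z"].append(float(leaf_z.loc[ts]))
                    corr_pairs["psi_stem"].append(float(row["psi_stem"]))
                    corr_pairs["psi_leaf"].append(float(row["psi_leaf"]))
        except Exception as exc:  # keep partial outputs, report the stage
            report.status = "partial"
            report.failures.append(f"{treatment}/{tree_id}/{stage_id}: {exc}")
            log.warning("series failed: %s", report.failures[-1])

    features = pd.concat(features_rows, ignore_index=True) if features_rows else pd.DataFrame()
    features.to_csv(out / "features.csv", index=False)
    report.outputs["features"] = "features.csv"
    report.n_series = len(keys)

    if not features.empty:
        keys_cols = ["treatment", "tree_id", "stage_id", "date", "window_kind"]
        merged = features[features["variable"] == "RGR"].merge(
            features[features["variable"] == "RPCR"], on=keys_cols, suffixes=("_fruit", "_leaf")
        )
        ratios = merged[keys_cols].copy()
        for stat in ("rsd", "max", "min", "sum"):
            den = merged[f"{stat}_leaf"]
            ratios[f"{stat}_ratio"] = (merged[f"{stat}_fruit"] / den).where(den.abs() > 0)
        ratios.to_csv(out / "feature_ratios.csv", index=False)
        report.outputs["feature_ratios"] = "feature_ratios.csv"

    loop_table = loop_metrics_table(loops)
    loop_table.to_csv(out / "loops.csv", index=False)
    report.outputs["loops"] = "loops.csv"

    # ---- correlations of standardized signals vs spot water status
    corr_rows = []
    frame = pd.DataFrame(corr_pairs)
    for signal in ("fruit_z", "leaf_z"):
        for indicator in ("psi_stem", "psi_leaf"):
            if len(frame) >= 3 and frame[signal].std() > 0 and frame[indicator].std() > 0:
                r, p, n = correlate(frame[signal], frame[indicator])
                corr_rows.append({"signal": signal, "indicator": indicator, "r": r, "p": p, "n": n})
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
    report.outputs["correlations"] = "correlations.csv"

    # ---- model fits
    models_out = {}
    try:
        mlr = fit_multilinear_psistem(spots)
        models_out["multilinear"] = mlr.to_dict()
    except Exception as exc:
        report.status = "partial"
        report.failures.append(f"multilinear fit: {exc}")

    pairs = tree_week_means(bundle.feature_pairs)
    try:
        exl = fit_expolinear(pairs["psi_stem_midday"], pairs["nocturnal_rsd_ratio"])
        models_out["expolinear"] = exl.to_dict()
        report.expolinear_params = exl.params.to_dict()
        thr = exl.threshold(config.threshold_fraction)
        report.threshold = thr.psi_threshold
        (out / "threshold.json").write_text(
            json.dumps({"psi_threshold": thr.psi_threshold, "criterion": thr.criterion, "fraction": thr.fraction}, indent=2)
        )
        report.outputs["threshold"] = "threshold.json"
    except Exception as exc:
        report.status = "partial"
        report.failures.append(f"expolinear fit: {exc}")

    (out / "models.json").write_text(json.dumps(models_out, indent=2, default=float))
    report.outputs["models"] = "models.json"

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "dielsense_version": __version__,
                "seed": config.seed,
                "config_hash": _config_hash(config),
                "status": report.status,
                "failures": report.failures,
                "parameters": {
                    "smoothing_window": config.smoothing_window,
                    "smoothing_degree": config.smoothing_degree,
                    "completeness_min": config.completeness_min,
                    "threshold_fraction": config.threshold_fraction,
                },
            },
            indent=2,
        )
    )
    report.outputs["run_log"] = "run_log.json"
    return report
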
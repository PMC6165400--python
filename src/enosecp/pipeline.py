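"""End-to-end run: simulate -> extract -> conformal predict -> benchmark.

:func:`run_pipeline` wires the library stages together, writes every numeric
artifact (dataset + manifest, feature matrix, CP report, calibration curve,
benchmark table), two convenience plots and a machine-readable run summary.
Identical configuration and seed reproduce the CSV artifacts byte-for-byte
(plots are not held to byte stability).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .benchmark import ClassifierSpec, run_benchmark
from .conformal import CPConfig, calibration_curve, loo_evaluate
from .features import FeatureConfig, build_feature_matrix
from .plots import confidence_credibility_scatter, pca_scatter
from .simulate import SimulationConfig, make_class_profiles, simulate_dataset

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "DEFAULT_SPECS"]

logger = logging.getLogger("enosecp")

DEFAULT_SPECS = (
    ClassifierSpec("knn", {"k": 1}),
    ClassifierSpec("lda"),
    ClassifierSpec("svm", {"kernel": "linear"}, standardize=True),
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; ``seed`` feeds every stochastic stage."""

    n_classes: int = 4
    n_sensors: int = 8
    separation: float = 1.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cp: CPConfig = field(default_factory=CPConfig)
    benchmark_specs: tuple = DEFAULT_SPECS
    pca_dims: tuple = (2,)
    epsilons: tuple = (0.05, 0.1, 0.2)
    output_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "features" in kwargs:
            fc = dict(kwargs["features"])
            for key in ("baseline_window", "integration_window", "ema_window",
                        "smoothing_factors"):
                if fc.get(key) is not None:
                    fc[key] = tuple(fc[key])
            kwargs["features"] = FeatureConfig(**fc)
        if "cp" in kwargs:
            kwargs["cp"] = CPConfig(**kwargs["cp"])
        if "benchmark_specs" in kwargs:
            kwargs["benchmark_specs"] = tuple(
                ClassifierSpec(
                    s["family"], dict(s.get("hyperparameters", {})),
                    bool(s.get("standardize", False)),
                )
                for s in kwargs["benchmark_specs"]
            )
        for key in ("pca_dims", "epsilons"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["benchmark_specs"] = [
            {"family": s.family, "hyperparameters": s.hyperparameters,
             "standardize": s.standardize}
            for s in self.benchmark_specs
        ]
        # plain lists/scalars only, so the dict is YAML/JSON serializable
        return json.loads(json.dumps(out))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(eio.load_yaml(path))


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run summary (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "plots").mkdir(exist_ok=True)
    sim = replace(config.simulation, seed=config.seed)

    def simulate():
        profiles = make_class_profiles(
            config.n_classes, config.n_sensors, config.separation,
            seed=config.seed, timescale=sim.timescale,
        )
        records = simulate_dataset(profiles, sim)
        eio.write_dataset(records, out / "dataset")
        logger.info("simulated %d records (%d sensors, %d points each)",
                    len(records), config.n_sensors, sim.n_timepoints)
        return records

    records = _stage("simulate")(simulate)

    def extract():
        fm = build_feature_matrix(records, config.features)
        eio.write_feature_matrix(fm, out / "features.csv")
        logger.info("feature matrix %d x %d", fm.n_samples, fm.n_features)
        return fm

    fm = _stage("extract")(extract)

    def conformal():
        preds, acc = loo_evaluate(fm, config.cp)
        report = eio.write_cp_report(preds, fm.labels, out / "cp_report.csv",
                                     include_p_values=True)
        errs = calibration_curve(fm, config.cp, config.epsilons)
        cal_path = out / "calibration.csv"
        pd.DataFrame({"epsilon": list(config.epsilons), "error_rate": errs}).to_csv(
            cal_path, index=False, float_format="%.17g"
        )
        confidence_credibility_scatter(
            report, out / "plots" / "confidence_credibility.png",
            title=f"CP-{config.cp.k}NN ({config.cp.p_value_mode} p-values)",
        )
        logger.info("CP-%dNN forced accuracy %.4f", config.cp.k, acc)
        return acc, errs

    cp_acc, cal_errs = _stage("conformal")(conformal)

    def benchmark():
        report = run_benchmark(fm, config.benchmark_specs, config.pca_dims,
                               seed=config.seed)
        eio.write_benchmark_report(report, out / "benchmark.csv")
        pca_scatter(fm, out / "plots" / "pca_scatter.png", title="PCA (2-D)")
        logger.info("benchmark: %d rows", len(report.table))
        return report

    bench = _stage("benchmark")(benchmark)

    summary = {
        "config": config.to_dict(),
        "n_records": len(records),
        "feature_matrix_shape": [fm.n_samples, fm.n_features],
        "feature_columns": fm.n_features,
        "cp_forced_accuracy": cp_acc,
        "calibration": {
            str(eps): float(err) for eps, err in zip(config.epsilons, cal_errs)
        },
        "benchmark": bench.table.drop(columns=["time_s"]).to_dict("records"),
        "artifacts": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
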
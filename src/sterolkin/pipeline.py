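"""End-to-end orchestration: generate -> split -> fit -> evaluate -> report.

A run directory contains the dataset (CSV), every fitted model (JSON), the
per-topology error-curve table (CSV), a metric report laid out per data-role
subset (learning / test / building / validation) with EJCR verdicts, and a
plain-text log.  All randomness derives from one master seed, so rerunning
with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import ann, evaluation, rsr, synthetic_data as sd

__all__ = ["PipelineConfig", "run_pipeline", "load_model", "evaluate_model", "SUBSETS"]

#: Report layout: metrics per subset, building = learning + test.
SUBSETS = {
    "learning": ("learning",),
    "test": ("test",),
    "building": ("learning", "test", "unassigned"),
    "validation": ("validation",),
}

# seed offsets per stage, derived from the master seed
_SPLIT_OFFSET = 1
_MLP_OFFSET = 10_000
_RBF_OFFSET = 1_000_000


@dataclass
class PipelineConfig:
    """Configuration of a full replication run."""

    temperatures: Sequence[float] = sd.DEFAULT_TEMPERATURES
    water_activities: Sequence[float] = sd.DEFAULT_WATER_ACTIVITIES
    validation_conditions: Sequence[tuple[float, float]] = sd.DEFAULT_VALIDATION_CONDITIONS
    sampling_interval: float = 6.0
    replicates: int = 3
    noise_sd: float = 0.1
    learning_fraction: float = 0.7
    coefficients: rsr.RSRCoefficients = field(default_factory=lambda: rsr.REFERENCE_COEFFICIENTS)
    run_rsr: bool = True
    mlp_hidden: Sequence[int] = tuple(range(2, 17))
    mlp_activations: Sequence[str] = ("logistic", "tanh", "exponential")
    rbf_hidden: Sequence[int] = tuple(range(2, 51))
    restarts: int = 25
    max_iterations: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "coefficients" in raw:
            raw["coefficients"] = rsr.RSRCoefficients(**raw["coefficients"])
        if "validation_conditions" in raw:
            raw["validation_conditions"] = [tuple(c) for c in raw["validation_conditions"]]
        return cls(**raw)


def load_model(path):
    """Load a model file (RSR fit or trained network) by sniffing its schema."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if "spec" in d and "network_type" in d.get("spec", {}):
        return ann.TrainedNetwork.from_dict(d)
    if "coefficients" in d:
        return rsr.RSRFit.from_dict(d)
    raise ValueError(f"unrecognised model file: {path}")


def evaluate_model(dataset: sd.DegradationDataset, predict_fn, confidence: float = 0.95) -> dict:
    """Metric report + EJCR verdict for each data-role subset (the published
    table layout: learning, test, building, validation)."""
    out = {}
    for name, roles in SUBSETS.items():
        x, y = dataset.arrays(roles)
        if len(y) < 3:
            continue
        pred = np.asarray(predict_fn(x), dtype=float)
        block = {"metrics": evaluation.compute_metrics(y, pred).to_dict()}
        try:
            block["ejcr"] = evaluation.ejcr_test(y, pred, confidence=confidence).to_dict()
        except Exception as exc:  # degenerate subsets still get their metrics
            block["ejcr"] = {"error": str(exc)}
        out[name] = block
    return out


def _write_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full pipeline and write a self-contained run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    stages: dict[str, str] = {}
    report: dict = {"seed": config.seed, "models": {}, "stages": stages}

    def log(msg: str) -> None:
        log_lines.append(msg)

    # -- generate + split ------------------------------------------------
    design = sd.build_storage_design(
        config.temperatures,
        config.water_activities,
        sampling_interval=config.sampling_interval,
        replicates=config.replicates,
        validation_conditions=config.validation_conditions,
    )
    dataset = sd.simulate_degradation(design, config.coefficients, config.noise_sd, seed=config.seed)
    log(f"stage=generate seed={config.seed} n={dataset.n} experiments={len(design.experiments)}")
    dataset = sd.split_learning_test(dataset, config.learning_fraction, seed=config.seed + _SPLIT_OFFSET)
    counts = dataset.role_counts()
    shares = sd.set_shares(dataset)
    log(
        f"stage=split seed={config.seed + _SPLIT_OFFSET} "
        f"learning={counts['learning']} test={counts['test']} validation={counts['validation']}"
    )
    dataset.to_csv(out / "dataset.csv")
    stages["generate"] = "ok"
    stages["split"] = "ok"
    report["n"] = dataset.n
    report["role_counts"] = counts
    report["shares"] = {"learning": shares.learning, "test": shares.test, "validation": shares.validation}

    curves_frames = []

    # -- RSR -------------------------------------------------------------
    if config.run_rsr:
        try:
            fit = rsr.fit_rsr(dataset)
            fit.save_json(out / "rsr_model.json")
            report["models"]["rsr"] = {
                "fit": fit.to_dict(),
                "evaluation": evaluate_model(dataset, fit.predict),
            }
            log(f"stage=fit_rsr n={fit.n} residual_se={fit.residual_standard_error:.6g}")
            stages["fit_rsr"] = "ok"
        except Exception as exc:
            stages["fit_rsr"] = f"failed: {exc}"
            log(f"stage=fit_rsr status=failed error={exc}")

    # -- ANN searches ----------------------------------------------------
    for kind, grid, offset in (
        ("mlp", ann.mlp_grid(config.mlp_hidden, config.mlp_activations) if config.mlp_hidden else [], _MLP_OFFSET),
        ("rbf", ann.rbf_grid(config.rbf_hidden) if config.rbf_hidden else [], _RBF_OFFSET),
    ):
        if not grid:
            continue
        try:
            result = ann.architecture_search(
                dataset,
                grid,
                restarts=config.restarts,
                base_seed=config.seed + offset,
                max_iterations=config.max_iterations,
            )
            result.best.save_json(out / f"{kind}_model.json")
            frame = result.curves.copy()
            curves_frames.append(frame)
            report["models"][kind] = {
                "spec": result.best.to_dict()["spec"],
                "errors": result.best.to_dict()["errors"],
                "weighted_error": result.best_weighted_error,
                "weights": list(result.weights),
                "restarts": result.restarts,
                "estimated_hidden": result.estimated_hidden,
                "evaluation": evaluate_model(dataset, result.best.predict),
            }
            log(
                f"stage=search_{kind} seed={config.seed + offset} restarts={result.restarts} "
                f"topologies={len(grid)} best={result.best.spec.label} "
                f"weighted_error={result.best_weighted_error:.6g}"
            )
            stages[f"search_{kind}"] = "ok"
        except Exception as exc:
            stages[f"search_{kind}"] = f"failed: {exc}"
            log(f"stage=search_{kind} status=failed error={exc}")

    if curves_frames:
        import pandas as pd

        pd.concat(curves_frames, ignore_index=True).to_csv(out / "error_curves.csv", index=False)

    # -- ranking ---------------------------------------------------------
    # validation-set quality first (RMSE ascending), weighted error as tie-break
    ranking = []
    for name, block in report["models"].items():
        val = block["evaluation"].get("validation", {}).get("metrics", {})
        ranking.append(
            {
                "model": name,
                "validation_rmse": val.get("RMSE"),
                "validation_r2": val.get("R2"),
                "weighted_error": block.get("weighted_error"),
            }
        )
    ranking.sort(
        key=lambda r: (
            r["validation_rmse"] if r["validation_rmse"] is not None else float("inf"),
            r["weighted_error"] if r["weighted_error"] is not None else float("inf"),
        )
    )
    report["ranking"] = ranking
    log("stage=report models=" + ",".join(r["model"] for r in ranking))

    _write_json(out / "report.json", report)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
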
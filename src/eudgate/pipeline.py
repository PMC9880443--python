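"""End-to-end pipeline driver: simulate → EUD/features → accumulate → predict.

A ``PipelineConfig`` (usually read from YAML) names the cohort conditions,
the output directory and which stages to run.  Every metrics file carries
the seed and a hash of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .accumulation import GammaCriteria, accumulate, gamma_pass_rate, pullback_dose
from .geometry import extract_features
from .grids import StructureMask
from .stats import FEATURE_SETS, lopo_random_forest, make_weights, nested_lopo_mlp
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_to_dir", "cohort_features"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str = "eudgate_out"
    stages: dict = field(
        default_factory=lambda: {
            "eud": True, "features": True, "accumulate": True,
            "gamma": False, "predict": True, "write_volumes": False,
        }
    )
    feature_sets: tuple[str, ...] = ("A", "F")
    models: tuple[str, ...] = ("rf",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.get("cohort") or {}).items()
        })
        kwargs = {k: v for k, v in raw.items() if k != "cohort"}
        for key in ("feature_sets", "models"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(cohort=cohort, **kwargs)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cohort": dataclasses.asdict(self.cohort),
                "stages": self.stages,
                "feature_sets": list(self.feature_sets),
                "models": list(self.models),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_to_dir(cfg: CohortConfig, out_dir, write_volumes: bool = True) -> list:
    """Generate a cohort and (optionally) write NIfTI volumes + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    manifest = {"seed": cfg.seed, "patients": []}
    for series in cohort:
        entry = {
            "patient_id": series.patient_id,
            "n_fractions": len(series.fractions),
            "prescription_Gy": series.prescription,
            "ctv_volume_cm3": series.ctv_plan.volume_cm3,
        }
        if write_volumes:
            pdir = out / series.patient_id
            pdir.mkdir(exist_ok=True)
            io.write_grid(pdir / "plan_dose.nii.gz", series.plan_dose)
            io.write_grid(pdir / "ctv_plan.nii.gz", series.ctv_plan)
            for i, (fld, ctv_i) in enumerate(series.fractions, start=1):
                io.write_grid(pdir / f"field_{i:03d}.nii.gz", fld)
                io.write_grid(pdir / f"ctv_{i:03d}.nii.gz", ctv_i)
            entry["dir"] = str(pdir)
        manifest["patients"].append(entry)
    io.write_json(out / "manifest.json", manifest)
    return cohort


def cohort_features(cohort) -> pd.DataFrame:
    return pd.concat([extract_features(s) for s in cohort], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return (and write) the metrics report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)

    t0 = time.time()
    cohort = simulate_to_dir(
        cohort_cfg, out, write_volumes=config.stages.get("write_volumes", False)
    )
    report["stages"]["simulate"] = {
        "seconds": round(time.time() - t0, 2),
        "n_patients": len(cohort),
        "n_fractions": int(sum(len(s.fractions) for s in cohort)),
    }

    features = None
    if config.stages.get("features", True) or config.stages.get("eud", True):
        t0 = time.time()
        features = cohort_features(cohort)
        features.to_csv(out / "features.csv", index=False)
        report["stages"]["features"] = {
            "seconds": round(time.time() - t0, 2),
            "n_rows": len(features),
            "geud_below_093": int((features["gEUD"] < 0.93).sum()),
            "median_geud": float(features["gEUD"].median()),
        }

    if config.stages.get("accumulate", True):
        t0 = time.time()
        acc_metrics = {}
        for series in cohort:
            _, geud_acc, dmin_acc = accumulate(series)
            acc_metrics[series.patient_id] = {
                "geud_acc": geud_acc, "dmin_acc": dmin_acc,
            }
        report["stages"]["accumulate"] = {
            "seconds": round(time.time() - t0, 2),
            "per_patient": acc_metrics,
        }

    if config.stages.get("gamma", False):
        t0 = time.time()
        series = cohort[0]
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(~series.ctv_plan.values, sampling=series.grid.spacing)
        roi = StructureMask(series.grid, dist <= 15.0)
        fld, _ = series.fractions[0]
        warped = pullback_dose(series.plan_dose, fld)
        rate = gamma_pass_rate(series.plan_dose, warped, GammaCriteria(), roi)
        report["stages"]["gamma"] = {
            "seconds": round(time.time() - t0, 2),
            "criteria": "3 mm / 3 %",
            "pass_rate": rate,
        }

    if config.stages.get("predict", True) and features is not None:
        t0 = time.time()
        weights = make_weights(features["gEUD"])
        pred_report = {}
        for fs_name in config.feature_sets:
            fset = FEATURE_SETS[fs_name]
            for model in config.models:
                if model == "rf":
                    res = lopo_random_forest(features, fset, weights, seed=config.seed)
                elif model == "mlp":
                    res = nested_lopo_mlp(features, fset, weights, seed=config.seed)
                else:
                    raise ValueError(f"unknown model {model!r}")
                key = f"{model}_{fs_name}"
                res.predictions.to_csv(out / f"predictions_{key}.csv", index=False)
                pred_report[key] = {
                    "pearson_r": res.pearson_r,
                    "fisher_ci": list(res.fisher_ci),
                    "ve_cv": res.ve_cv,
                }
                if res.importance is not None:
                    res.importance.to_csv(out / f"importance_{key}.csv")
                    pred_report[key]["top_feature"] = str(res.importance.index[0])
        report["stages"]["predict"] = {
            "seconds": round(time.time() - t0, 2), **pred_report,
        }

    io.write_json(out / "metrics.json", report)
    return report
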
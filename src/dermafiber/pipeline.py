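"""Per-sample and cohort orchestration.

A sample run chains preprocess → orientation → directional summary → von
Mises fit → density (per channel) plus mechanics, producing one feature row;
a cohort run assembles the rows, filters complete cases and screens pairwise
dependencies.  Failures in one stage are recorded and the rest proceed, so a
sample without a tensile log still yields its structural columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import depstats, fiber_metrics, mechanics, orientation3d, stack_io, vonmises

log = logging.getLogger("dermafiber")


@dataclass
class RunConfig:
    samples: list = field(default_factory=list)
    window_size: int = orientation3d.DEFAULT_WINDOW
    threshold_factor: float = fiber_metrics.DEFAULT_FACTOR
    apply_clahe: bool = True
    clip_fov: bool = False
    n_resamples: int = depstats.DEFAULT_RESAMPLES
    alpha: float = depstats.DEFAULT_ALPHA
    seed: int = 0
    out_dir: str = "dermafiber_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: v for k, v in config.__dict__.items()}, default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_channel_stack(stack: stack_io.ImageStack, config: RunConfig) -> dict:
    """Structural features of one channel: density, 3DOI, angles, mixture fit."""
    density = fiber_metrics.fiber_density(stack, config.threshold_factor)
    work = stack_io.clahe_enhance(stack) if config.apply_clahe else stack
    field_ = orientation3d.estimate_orientation(
        work, config.window_size, config.threshold_factor)
    summary = orientation3d.directional_summary(field_)
    hist = orientation3d.layer_histograms(field_)
    fit = vonmises.vm_fit(hist)
    return {
        "density": density,
        "oi3d": summary.oi3d,
        "main_theta": summary.main_theta,
        "main_theta_folded": summary.main_theta_folded,
        "main_phi": summary.main_phi,
        "n_valid": summary.n_valid,
        "vonmises": fit.params.__dict__,
        "vonmises_rss": fit.rss,
        "vonmises_degenerate": fit.degenerate_second_family,
        "histogram": hist,
        "field": field_,
    }


def run_sample(entry: dict, config: RunConfig | None = None) -> dict:
    """Analyze one sample described by a config entry.

    Entry keys: ``sample_id``, optional ``collagen``/``elastin`` (TIFF paths
    or in-memory ImageStacks), optional ``tensile`` (CSV path or DataFrame),
    optional ``age``, ``T_CO``, ``T_EL`` metadata, optional ``geometry``.
    Missing inputs leave the corresponding feature columns as NaN.
    """
    config = config or RunConfig()
    row: dict = {"sample_id": entry.get("sample_id", "")}
    errors: dict = {}
    suffix = {"collagen": "CO", "elastin": "EL"}
    for channel in ("collagen", "elastin"):
        src = entry.get(channel)
        sfx = suffix[channel]
        if src is None:
            row.update({f"D_{sfx}": np.nan, f"OI3D_{sfx}": np.nan,
                        f"main_theta_{sfx}": np.nan})
            continue
        try:
            t0 = time.perf_counter()
            stack = src if isinstance(src, stack_io.ImageStack) else \
                stack_io.read_stack(src, channel=channel)
            if config.clip_fov:
                stack = stack_io.clip_fov(stack)
            res = analyze_channel_stack(stack, config)
            row[f"D_{sfx}"] = res["density"]
            row[f"OI3D_{sfx}"] = res["oi3d"]
            row[f"main_theta_{sfx}"] = res["main_theta_folded"]
            row[f"vonmises_{sfx}"] = res["vonmises"]
            log.info("%s/%s analyzed in %.1fs", row["sample_id"], channel,
                     time.perf_counter() - t0)
        except Exception as exc:  # stage failure: record and continue
            errors[channel] = str(exc)
            row.update({f"D_{sfx}": np.nan, f"OI3D_{sfx}": np.nan,
                        f"main_theta_{sfx}": np.nan})
    tensile = entry.get("tensile")
    mech_cols = ("E1", "E2", "sigma_max", "eps_max", "eps_mid")
    if tensile is None:
        row.update({c: np.nan for c in mech_cols})
    else:
        try:
            if isinstance(tensile, mechanics.StressStrainCurve):
                curve = tensile
            else:
                df = tensile if isinstance(tensile, pd.DataFrame) else \
                    stack_io.read_table(tensile)
                geom = entry.get("geometry") or mechanics.SampleGeometry()
                curve = mechanics.build_curve(df["displacement_mm"],
                                              df["force_N"], geom)
            chars = mechanics.extract_characteristics(curve)
            for c in mech_cols:
                row[c] = getattr(chars, c)
        except Exception as exc:
            errors["tensile"] = str(exc)
            row.update({c: np.nan for c in mech_cols})
    for meta in ("age", "T_CO", "T_EL"):
        row[meta] = entry.get(meta, np.nan)
    row["errors"] = errors
    return row


def run_cohort(config: RunConfig) -> dict:
    """Full cohort analysis: feature table, dependency screen, manifest."""
    rows = [run_sample(entry, config) for entry in config.samples]
    drop = {"vonmises_CO", "vonmises_EL", "errors"}
    table = pd.DataFrame([{k: v for k, v in r.items() if k not in drop}
                          for r in rows])
    # only screen features that are populated for at least one sample
    # (a cohort without, say, elastin stacks must not empty the table)
    features = [c for c in depstats.FEATURE_COLUMNS
                if c in table.columns and table[c].notna().any()]
    report: dict = {"n_samples": len(table)}
    dependencies: list = []
    if len(table) >= 4:
        usable = depstats.complete_cases(table, features)
        report["n_complete"] = len(usable)
        dependencies = depstats.pairwise_dependencies(
            table, features, alpha=config.alpha,
            n_resamples=config.n_resamples, seed=config.seed)
    else:
        report["dependency_stage"] = "skipped: fewer than 4 samples"
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples": len(table),
        "warnings": [r["errors"] for r in rows if r["errors"]],
    }
    return {"table": table, "dependencies": dependencies,
            "report": report, "manifest": manifest, "rows": rows}


def write_outputs(result: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result["table"].to_csv(os.path.join(out_dir, "features.csv"), index=False)
    deps = pd.DataFrame([d.__dict__ for d in result["dependencies"]])
    deps.to_csv(os.path.join(out_dir, "dependencies.csv"), index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result["manifest"], fh, indent=2, default=str)
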
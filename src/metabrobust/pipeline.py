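"""Configuration-driven workflows wiring the stages end to end.

Two workflows mirror the two halves of a method-development study:

``run_comparison``
    read peak lists -> noise filter -> align -> blank filter -> per-method
    all-replicate presence -> CV classification -> method summaries and
    exclusive overlap counts.

``run_robustness``
    validate the screening design -> read/align/filter the batch -> join to
    the design on the log scale -> fit the hierarchical factor-effect model
    -> coefficient tables with percent-change interpretation -> QC drift
    check.

Both are driven by one YAML config, write machine-readable reports plus a
provenance record (config hash, seed, package version) to the output
directory, and are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .comparison import intersection_counts, summarize_methods
from .design import load_table1_design, read_design_csv, read_factor_specs, validate_design
from .features import align_features, noise_filter, read_peak_lists, write_feature_table
from .filtering import drop_blank_features, run_filter_cascade
from .robustness import (
    ModelConfig,
    assemble_robustness_dataset,
    fit_per_metabolite_model,
    fit_pooled_model,
    qc_drift_check,
)

__all__ = ["PipelineConfig", "run_comparison", "run_robustness"]

log = logging.getLogger("metabrobust")


@dataclass
class PipelineConfig:
    """One YAML config drives either workflow; thresholds default to the
    standard values (200-count noise floor, 15 ppm, 0.15 min, 20% CV)."""

    peaks: str
    metadata: str
    output_dir: str
    design: str | None = None  # coded design CSV, or "table1" for the packaged worksheet
    factors: str | None = None  # factor spec CSV for decoding, optional
    noise_threshold: float = 200.0
    ppm_tol: float = 15.0
    rt_tol_min: float = 0.15
    cv_threshold_pct: float = 20.0
    qc_slope_threshold: float = 0.01
    model: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("noise_threshold", "ppm_tol", "rt_tol_min", "cv_threshold_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _check_inputs(config: PipelineConfig, *paths: str | None) -> None:
    for p in paths:
        if p is not None and p != "table1" and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")


def _provenance(config_path: str | Path, config: PipelineConfig, workflow: str) -> dict:
    return {
        "workflow": workflow,
        "package_version": __version__,
        "config_path": str(config_path),
        "config_sha256": _config_hash(config_path),
        "seed": config.seed,
    }


def _load_design(config: PipelineConfig):
    if config.design == "table1":
        return load_table1_design()
    factors = read_factor_specs(config.factors) if config.factors else None
    return read_design_csv(config.design, factors=factors)


def _prepare_table(config: PipelineConfig):
    peaklists = read_peak_lists(config.peaks, config.metadata)
    peaklists = [noise_filter(pl, config.noise_threshold) for pl in peaklists]
    return align_features(peaklists, ppm_tol=config.ppm_tol, rt_tol_min=config.rt_tol_min)


def run_comparison(config_path: str | Path) -> dict[str, Any]:
    """Extraction-method comparison workflow; returns the report bundle."""
    config = PipelineConfig.from_yaml(config_path)
    logging.basicConfig(level=config.log_level)
    _check_inputs(config, config.peaks, config.metadata)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = _prepare_table(config)
    log.info("aligned %d features across %d samples", table.n_features, len(table.sample_ids))
    clean = drop_blank_features(table)
    study = table.samples[table.samples["role"] == "study"]
    method_groups = {str(m): list(g.index) for m, g in study.groupby("method", sort=True)}

    summary = summarize_methods(clean, method_groups, config.cv_threshold_pct)
    overlaps = intersection_counts(summary.feature_sets)
    reports = {}
    for method, sample_ids in method_groups.items():
        _, report, _ = run_filter_cascade(
            table, sample_ids, group=method, cv_threshold_pct=config.cv_threshold_pct
        )
        reports[method] = report.stage_counts

    write_feature_table(table, out / "feature_table.csv")
    summary.to_json(out / "comparison_summary.json")
    summary.to_frame().to_csv(out / "comparison_summary.csv")
    overlaps.to_json(out / "intersection_counts.json")
    overlaps.to_frame().to_csv(out / "intersection_counts.csv", index=False)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(_provenance(config_path, config, "comparison"), fh, indent=2)
    return {"summary": summary, "intersections": overlaps, "filter_reports": reports}


def run_robustness(config_path: str | Path) -> dict[str, Any]:
    """Robustness workflow: design validation, model fit, QC drift check."""
    config = PipelineConfig.from_yaml(config_path)
    logging.basicConfig(level=config.log_level)
    if config.design is None:
        raise ValueError("robustness workflow requires a design")
    _check_inputs(config, config.peaks, config.metadata, config.design)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = _load_design(config)
    report = validate_design(design)
    with open(out / "design_validation.json", "w") as fh:
        json.dump(
            {
                "ok": report.ok,
                "balanced": report.balanced,
                "orthogonal": {f"{a}|{b}": v for (a, b), v in report.orthogonal.items()},
                "messages": report.messages,
            },
            fh,
            indent=2,
        )
    if not report.ok:
        raise ValueError(
            "design failed validation (see design_validation.json): "
            + "; ".join(report.messages)
        )

    table = _prepare_table(config)
    clean = drop_blank_features(table)
    dataset = assemble_robustness_dataset(clean, design)
    log.info(
        "modelling %d features over %d runs (%d excluded for missingness)",
        dataset.n_metabolites, dataset.n_runs, len(dataset.excluded),
    )
    model_cfg = ModelConfig(seed=config.seed, **config.model)
    if model_cfg.variant == "per_metabolite":
        estimates = fit_per_metabolite_model(dataset, model_cfg)
    else:
        estimates = fit_pooled_model(dataset, model_cfg)
    estimates.to_csv(out / "effect_estimates.csv")
    estimates.to_json(out / "effect_estimates.json")

    drift = None
    if len(table.samples_with_role("qc")) >= 3:
        drift = qc_drift_check(table, slope_threshold=config.qc_slope_threshold)
        drift.to_json(out / "qc_drift.json")

    with open(out / "exclusions.json", "w") as fh:
        json.dump({"excluded_for_missingness": dataset.excluded}, fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(_provenance(config_path, config, "robustness"), fh, indent=2)
    return {"estimates": estimates, "drift": drift, "design_validation": report}
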
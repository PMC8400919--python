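"""Seeded synthetic LC-MS data with known ground truth.

The generator emulates the structure of an untargeted LC-MS batch so every
pipeline stage is testable without instrument data: log-normal baseline
abundances, multiplicative replicate noise calibrated to a target CV,
solvent-contaminant features that show up in blanks, stochastic dropout,
bounded m/z (ppm) and retention-time jitter, design-driven multiplicative
factor effects on the log scale, and pooled-QC injections with optional
signal drift.

The log-scale noise standard deviation is ``sqrt(ln(1 + (cv/100)^2))`` so a
log-normal multiplicative error reproduces the target percent CV exactly in
expectation.  Jitter is uniform within plus/minus the stated scale, so
"within half the alignment tolerances" is a hard guarantee, not a
probabilistic one.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .features import PeakList

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "cv_to_log_sd",
    "simulate_robustness_experiment",
    "simulate_method_comparison",
]


def cv_to_log_sd(cv_pct: float) -> float:
    """Log-scale noise sd giving a log-normal with the target percent CV."""
    if cv_pct < 0:
        raise ValueError("cv_pct must be >= 0")
    r = cv_pct / 100.0
    return math.sqrt(math.log1p(r * r))


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated experiment (or one method).

    Defaults mirror a typical tumour-extract LC-MS batch: on the order of a
    thousand features, median abundance around ``e^9.2`` (~10^4 counts,
    comfortably above the 200-count noise floor) spanning ~3 decades,
    replicate CV 15%, light dropout, a few dozen solvent contaminants, and
    m/z / RT jitter well inside the 15 ppm / 0.15 min alignment windows.
    """

    n_features: int = 1000
    baseline_log_mean: float = 9.2
    baseline_log_sd: float = 1.5
    cv_pct: float = 15.0
    betas: dict[str, float] = field(default_factory=dict)  # factor name -> log-scale effect
    dropout: float = 0.05
    n_blank_contaminants: int = 50
    mz_range: tuple[float, float] = (61.0, 1200.0)
    rt_range: tuple[float, float] = (0.5, 38.0)
    mz_jitter_ppm: float = 5.0
    rt_jitter_min: float = 0.05
    n_blanks: int = 2
    qc_every: int = 4
    qc_drift_per_injection: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.cv_pct < 0:
            raise ValueError("cv_pct must be >= 0")
        if self.n_blank_contaminants < 0:
            raise ValueError("n_blank_contaminants must be >= 0")
        if not self.mz_range[0] < self.mz_range[1] or self.mz_range[0] <= 0:
            raise ValueError("invalid mz_range")
        if not self.rt_range[0] < self.rt_range[1] or self.rt_range[0] < 0:
            raise ValueError("invalid rt_range")
        if self.mz_jitter_ppm < 0 or self.rt_jitter_min < 0:
            raise ValueError("jitter scales must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knew before noise was applied."""

    features: pd.DataFrame  # index feature id; mz, rt, baseline_log, is_contaminant
    betas: dict[str, float]
    contaminant_ids: list[str]
    dropout: dict[str, list[str]]  # sample id -> dropped feature ids
    config: SimulationConfig

    @property
    def n_true_features(self) -> int:
        return int((~self.features["is_contaminant"]).sum())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": {
                fid: {
                    "mz": float(r["mz"]),
                    "rt": float(r["rt"]),
                    "baseline_log": float(r["baseline_log"]),
                    "is_contaminant": bool(r["is_contaminant"]),
                }
                for fid, r in self.features.iterrows()
            },
            "betas": self.betas,
            "contaminant_ids": self.contaminant_ids,
            "dropout": self.dropout,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _seed_features(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n_true = config.n_features
    n_cont = config.n_blank_contaminants
    total = n_true + n_cont
    mz = rng.uniform(*config.mz_range, size=total)
    rt = rng.uniform(*config.rt_range, size=total)
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=total)
    ids = [f"T{i + 1:05d}" for i in range(n_true)] + [f"C{i + 1:04d}" for i in range(n_cont)]
    return pd.DataFrame(
        {
            "mz": mz,
            "rt": rt,
            "baseline_log": base,
            "is_contaminant": [False] * n_true + [True] * n_cont,
        },
        index=pd.Index(ids, name="feature_id"),
    )


def _observe(
    rng: np.random.Generator,
    feats: pd.DataFrame,
    log_abundance: np.ndarray,
    config: SimulationConfig,
    keep: np.ndarray | None = None,
) -> pd.DataFrame:
    """Materialize one injection: jittered (mz, rt, abundance) rows."""
    n = len(feats)
    mask = np.ones(n, dtype=bool) if keep is None else keep
    mz = feats["mz"].to_numpy(float)[mask]
    rt = feats["rt"].to_numpy(float)[mask]
    mz = mz * (1.0 + rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm, mz.size) * 1e-6)
    rt = np.clip(rt + rng.uniform(-config.rt_jitter_min, config.rt_jitter_min, rt.size), 0.0, None)
    return pd.DataFrame({"mz": mz, "rt": rt, "abundance": np.exp(log_abundance[mask])})


def simulate_robustness_experiment(
    design: DesignMatrix, config: SimulationConfig
) -> tuple[list[PeakList], GroundTruth]:
    """Simulate one screening batch: a sample per design run, blanks and QCs.

    Study abundance of feature ``m`` in run ``i`` is
    ``exp(baseline[m] + sum_f beta[f] * x[i,f] + noise)``; contaminant
    features ignore the design and also appear in blanks.  A pooled QC
    injection is inserted after every ``qc_every`` study samples (always
    from the same pool, so only injection noise and optional drift vary).
    """
    rng = np.random.default_rng(config.seed)
    feats = _seed_features(rng, config)
    is_cont = feats["is_contaminant"].to_numpy()
    base = feats["baseline_log"].to_numpy(float)
    sd = cv_to_log_sd(config.cv_pct)

    unknown = [f for f in config.betas if f not in design.factor_names]
    if unknown:
        raise ValueError(f"betas refer to unknown factors: {unknown}")
    beta_vec = np.array([config.betas.get(f, 0.0) for f in design.factor_names])

    peaklists: list[PeakList] = []
    dropout_log: dict[str, list[str]] = {}
    qc_pool = base.copy()  # same vial throughout the batch
    order = 0
    since_qc = 0
    n_qc = 0

    def add_qc() -> None:
        nonlocal order, n_qc
        order += 1
        n_qc += 1
        noise = rng.normal(0.0, sd, base.size)
        log_ab = qc_pool + noise + config.qc_drift_per_injection * order
        sid = f"QC{n_qc:02d}"
        peaklists.append(
            PeakList(
                sample_id=sid,
                role="qc",
                injection_order=order,
                peaks=_observe(rng, feats, log_ab, config),
            )
        )

    for run in design.runs:
        x = np.array(run.levels, dtype=float)
        shift = float(x @ beta_vec)
        log_ab = base + np.where(is_cont, 0.0, shift) + rng.normal(0.0, sd, base.size)
        keep = rng.random(base.size) >= config.dropout
        order += 1
        sid = f"R{run.run_id}"
        dropped = feats.index[~keep].tolist()
        if dropped:
            dropout_log[sid] = dropped
        peaklists.append(
            PeakList(
                sample_id=sid,
                role="study",
                design_run=run.run_id,
                injection_order=order,
                peaks=_observe(rng, feats, log_ab, config, keep),
            )
        )
        since_qc += 1
        if config.qc_every and since_qc % config.qc_every == 0:
            add_qc()
    if config.qc_every and n_qc < 3:
        while n_qc < 3:  # drift needs at least 3 points
            add_qc()

    for b in range(config.n_blanks):
        order += 1
        log_ab = base + rng.normal(0.0, sd, base.size)
        peaklists.append(
            PeakList(
                sample_id=f"BLANK{b + 1:02d}",
                role="blank",
                injection_order=order,
                peaks=_observe(rng, feats, log_ab, config, keep=is_cont.copy()),
            )
        )

    truth = GroundTruth(
        features=feats,
        betas=dict(config.betas),
        contaminant_ids=feats.index[is_cont].tolist(),
        dropout=dropout_log,
        config=config,
    )
    return peaklists, truth


def simulate_method_comparison(
    configs: Mapping[str, SimulationConfig],
    n_replicates: int = 3,
    universe_size: int | None = None,
    subsets: Mapping[str, Sequence[int]] | None = None,
    seed: int | None = None,
) -> tuple[list[PeakList], GroundTruth]:
    """Simulate an extraction-method comparison over a shared feature universe.

    Each method detects a subset of the universe (drawn at random, or given
    explicitly via ``subsets`` as universe indices for controlled overlap)
    and measures it in ``n_replicates`` replicate extractions with its own
    CV and dropout.  Universe-level contaminants appear in every sample and
    in the shared blanks.
    """
    if not configs:
        raise ValueError("need at least one method config")
    first = next(iter(configs.values()))
    rng = np.random.default_rng(first.seed if seed is None else seed)
    universe_size = universe_size or max(c.n_features for c in configs.values())
    if any(c.n_features > universe_size for c in configs.values()):
        raise ValueError("method n_features exceeds universe_size")
    uni_cfg = SimulationConfig(
        n_features=universe_size,
        baseline_log_mean=first.baseline_log_mean,
        baseline_log_sd=first.baseline_log_sd,
        n_blank_contaminants=first.n_blank_contaminants,
        mz_range=first.mz_range,
        rt_range=first.rt_range,
        seed=first.seed,
    )
    feats = _seed_features(rng, uni_cfg)
    is_cont = feats["is_contaminant"].to_numpy()
    base = feats["baseline_log"].to_numpy(float)
    true_idx = np.flatnonzero(~is_cont)

    method_members: dict[str, np.ndarray] = {}
    for method, cfg in configs.items():
        if subsets is not None and method in subsets:
            chosen = np.asarray(list(subsets[method]), dtype=int)
            if chosen.size and (chosen.min() < 0 or chosen.max() >= universe_size):
                raise ValueError(f"subset indices for {method!r} outside the universe")
            chosen = true_idx[chosen]
        else:
            chosen = rng.choice(true_idx, size=cfg.n_features, replace=False)
        member = np.zeros(len(feats), dtype=bool)
        member[chosen] = True
        member |= is_cont  # contaminants contaminate everything
        method_members[method] = member

    peaklists: list[PeakList] = []
    dropout_log: dict[str, list[str]] = {}
    order = 0
    for method, cfg in sorted(configs.items()):
        sd = cv_to_log_sd(cfg.cv_pct)
        member = method_members[method]
        for rep in range(1, n_replicates + 1):
            order += 1
            keep = member & (rng.random(len(feats)) >= cfg.dropout)
            log_ab = base + rng.normal(0.0, sd, base.size)
            sid = f"{method}_r{rep}"
            dropped = feats.index[member & ~keep].tolist()
            if dropped:
                dropout_log[sid] = dropped
            peaklists.append(
                PeakList(
                    sample_id=sid,
                    role="study",
                    method=method,
                    replicate=rep,
                    injection_order=order,
                    peaks=_observe(rng, feats, log_ab, cfg, keep),
                )
            )
    for b in range(first.n_blanks):
        order += 1
        log_ab = base + rng.normal(0.0, cv_to_log_sd(first.cv_pct), base.size)
        peaklists.append(
            PeakList(
                sample_id=f"BLANK{b + 1:02d}",
                role="blank",
                injection_order=order,
                peaks=_observe(rng, feats, log_ab, first, keep=is_cont.copy()),
            )
        )

    truth = GroundTruth(
        features=feats,
        betas={},
        contaminant_ids=feats.index[is_cont].tolist(),
        dropout=dropout_log,
        config=first,
    )
    # record the per-method true subsets alongside the universe
    truth.features = truth.features.copy()
    for method, member in method_members.items():
        truth.features[f"in_{method}"] = member & ~is_cont
    return peaklists, truth
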
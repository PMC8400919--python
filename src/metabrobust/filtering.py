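"""Feature-quality cascade: blank exclusion, replicate presence, CV classification.

Untargeted feature tables are noisy; before any comparison or modelling the
standard cascade is applied:

1. discard every feature detected in any solvent-blank sample
   (contamination from solvents, reagents or labware);
2. keep a feature for a group (extraction method or design batch) only when
   it is detected in *all* replicates of that group;
3. classify features as reproducible when their percent coefficient of
   variation (CV) across replicates is strictly below a threshold
   (20% by convention).

Stage counts are monotonically non-increasing; the report records them and
the rule that removed each feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = [
    "FeatureStats",
    "FilterReport",
    "drop_blank_features",
    "replicate_presence_filter",
    "feature_cv",
    "group_feature_stats",
    "reproducible_features",
    "run_filter_cascade",
]


@dataclass(frozen=True)
class FeatureStats:
    """Replicate statistics of one feature within one group."""

    feature_id: str
    group: str
    n_detected: int
    mean_abundance: float
    cv_pct: float | None  # None when undefined (n_detected < 2 or zero mean)


@dataclass
class FilterReport:
    """Stage counts and per-feature dispositions of one cascade run."""

    stage_counts: dict[str, int]
    removed: dict[str, str] = field(default_factory=dict)  # feature id -> removing rule

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stage_counts": self.stage_counts, "removed": self.removed}, fh, indent=2)


def drop_blank_features(
    table: FeatureTable, blank_sample_ids: Sequence[str] | None = None
) -> FeatureTable:
    """Remove features detected in any blank sample, then drop blank columns.

    Detection means any non-missing abundance; a feature seen in even one
    blank is treated as contamination outright (no fold-change rule).
    """
    if blank_sample_ids is None:
        blank_sample_ids = table.samples_with_role("blank")
    blanks = list(blank_sample_ids)
    unknown = [s for s in blanks if s not in table.abundance.columns]
    if unknown:
        raise KeyError(f"unknown blank sample ids: {unknown}")
    if blanks:
        contaminated = table.abundance[blanks].notna().any(axis=1)
    else:
        contaminated = pd.Series(False, index=table.abundance.index)
    keep_features = table.abundance.index[~contaminated]
    keep_samples = [s for s in table.abundance.columns if s not in set(blanks)]
    return table.subset_features(keep_features).subset_samples(keep_samples)


def replicate_presence_filter(table: FeatureTable, group_sample_ids: Sequence[str]) -> set[str]:
    """Feature ids detected (non-missing) in *every* sample of the group.

    With a single replicate, presence in that one sample suffices (degenerate
    case; a warning is emitted because no spread can be assessed).
    """
    ids = list(group_sample_ids)
    if not ids:
        raise ValueError("group has no samples")
    if len(ids) == 1:
        import warnings

        warnings.warn("group has a single replicate; presence filter is degenerate")
    present = table.abundance[ids].notna().all(axis=1)
    return set(table.abundance.index[present])


def feature_cv(abundances: Iterable[float]) -> float:
    """Percent coefficient of variation: 100 * sample SD (n-1) / mean.

    Requires at least two non-missing values and a non-zero mean.
    """
    x = np.asarray(list(abundances), dtype=float)
    if x.size < 2:
        raise ValueError("CV undefined for fewer than 2 values")
    if np.isnan(x).any():
        raise ValueError("CV input contains missing values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def group_feature_stats(
    table: FeatureTable, group: str, group_sample_ids: Sequence[str]
) -> list[FeatureStats]:
    """Per-feature replicate statistics (detection count, mean, CV) for a group."""
    ids = list(group_sample_ids)
    sub = table.abundance[ids]
    out = []
    for fid, row in sub.iterrows():
        vals = row.dropna().to_numpy(float)
        n = int(vals.size)
        mean = float(vals.mean()) if n else float("nan")
        cv = None
        if n >= 2 and mean != 0:
            cv = float(100.0 * vals.std(ddof=1) / mean)
        out.append(FeatureStats(str(fid), group, n, mean, cv))
    return out


def reproducible_features(
    stats: Sequence[FeatureStats], cv_threshold_pct: float = 20.0
) -> set[str]:
    """Feature ids whose CV is defined and strictly below the threshold."""
    return {
        s.feature_id for s in stats if s.cv_pct is not None and s.cv_pct < cv_threshold_pct
    }


def run_filter_cascade(
    table: FeatureTable,
    group_sample_ids: Sequence[str],
    group: str = "group",
    blank_sample_ids: Sequence[str] | None = None,
    cv_threshold_pct: float = 20.0,
) -> tuple[set[str], FilterReport, list[FeatureStats]]:
    """Blank filter -> all-replicate presence -> CV classification for one group.

    Returns the reproducible feature ids, a :class:`FilterReport` with the
    monotone stage counts, and the per-feature statistics of the presence-
    filtered features.
    """
    report = FilterReport(stage_counts={"input": table.n_features})
    clean = drop_blank_features(table, blank_sample_ids)
    for fid in table.abundance.index.difference(clean.abundance.index):
        report.removed[str(fid)] = "detected_in_blank"
    report.stage_counts["post_blank"] = clean.n_features

    present = replicate_presence_filter(clean, group_sample_ids)
    for fid in clean.abundance.index:
        if fid not in present:
            report.removed[str(fid)] = "not_in_all_replicates"
    report.stage_counts["all_replicates"] = len(present)

    stats = group_feature_stats(clean.subset_features(sorted(present)), group, group_sample_ids)
    repro = reproducible_features(stats, cv_threshold_pct)
    for s in stats:
        if s.feature_id not in repro:
            report.removed[s.feature_id] = "cv_at_or_above_threshold"
    report.stage_counts["reproducible"] = len(repro)

    counts = list(report.stage_counts.values())
    assert all(a >= b for a, b in zip(counts, counts[1:])), "cascade counts must be monotone"
    return repro, report, stats
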
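"""Extraction-method comparison: counts, reproducibility and set overlaps.

Methods are compared on (i) how many features they extract — a feature
counts for a method only when detected in all of that method's replicates —
(ii) how many of those are reproducible (CV < 20%), (iii) the mean CV over
extracted features, and (iv) the exclusive overlap structure of the
per-method feature sets (UpSet semantics: each feature counts toward exactly
the subset of methods that detected it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable
from .filtering import group_feature_stats, replicate_presence_filter, reproducible_features

__all__ = [
    "MethodSummary",
    "ComparisonSummary",
    "IntersectionCounts",
    "summarize_methods",
    "intersection_counts",
    "plot_upset",
]


@dataclass(frozen=True)
class MethodSummary:
    method: str
    n_extracted: int
    n_reproducible: int
    mean_cv_pct: float  # mean over extracted features with a defined CV

    def __post_init__(self) -> None:
        if self.n_reproducible > self.n_extracted:
            raise ValueError("reproducible count cannot exceed extracted count")


@dataclass
class ComparisonSummary:
    """Per-method totals plus the underlying extracted feature id sets."""

    methods: dict[str, MethodSummary]
    feature_sets: dict[str, set[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": m.method,
                    "n_extracted": m.n_extracted,
                    "n_reproducible": m.n_reproducible,
                    "mean_cv_pct": m.mean_cv_pct,
                }
                for m in self.methods.values()
            ]
        ).set_index("method")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    m: {
                        "n_extracted": s.n_extracted,
                        "n_reproducible": s.n_reproducible,
                        "mean_cv_pct": s.mean_cv_pct,
                    }
                    for m, s in self.methods.items()
                },
                fh,
                indent=2,
            )


@dataclass
class IntersectionCounts:
    """Exclusive combination counts over method feature sets (UpSet semantics)."""

    counts: dict[frozenset, int]
    set_sizes: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())

    def count(self, *methods: str) -> int:
        return self.counts.get(frozenset(methods), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combination": "&".join(sorted(k)), "degree": len(k), "count": v}
            for k, v in self.counts.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["degree", "combination"])
            .reset_index(drop=True)
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "set_sizes": self.set_sizes,
                    "exclusive_counts": {
                        "&".join(sorted(k)): v for k, v in self.counts.items()
                    },
                },
                fh,
                indent=2,
            )


def summarize_methods(
    table: FeatureTable,
    method_groups: Mapping[str, Sequence[str]] | None = None,
    cv_threshold_pct: float = 20.0,
) -> ComparisonSummary:
    """Per-method extracted/reproducible counts and mean CV.

    ``method_groups`` maps a method label to its replicate sample ids; by
    default it is derived from the table's sample metadata (study samples
    grouped by ``method``).  Extracted means present in all replicates; the
    mean CV averages over extracted features whose CV is defined (features
    detected in fewer than 2 replicates cannot contribute a CV and are
    excluded from the average).
    """
    if method_groups is None:
        study = table.samples[table.samples["role"] == "study"]
        if study["method"].isna().all():
            raise ValueError("no method labels in sample metadata and no groups given")
        method_groups = {
            str(m): list(g.index) for m, g in study.groupby("method", sort=True)
        }
    summaries: dict[str, MethodSummary] = {}
    feature_sets: dict[str, set[str]] = {}
    for method, sample_ids in method_groups.items():
        if not list(sample_ids):
            raise ValueError(f"method {method!r} has no samples")
        extracted = replicate_presence_filter(table, sample_ids)
        stats = group_feature_stats(
            table.subset_features(sorted(extracted)), method, sample_ids
        )
        repro = reproducible_features(stats, cv_threshold_pct)
        cvs = [s.cv_pct for s in stats if s.cv_pct is not None]
        summaries[method] = MethodSummary(
            method=method,
            n_extracted=len(extracted),
            n_reproducible=len(repro),
            mean_cv_pct=float(np.mean(cvs)) if cvs else float("nan"),
        )
        feature_sets[method] = extracted
    return ComparisonSummary(methods=summaries, feature_sets=feature_sets)


def intersection_counts(feature_sets: Mapping[str, set]) -> IntersectionCounts:
    """Exclusive subset counts: each feature tallies toward exactly the
    combination of methods that contain it.

    Every non-empty combination is reported, including zero counts, and the
    counts sum to the size of the union of all sets.
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    names = sorted(feature_sets)
    counts: dict[frozenset, int] = {
        frozenset(c): 0 for r in range(1, len(names) + 1) for c in combinations(names, r)
    }
    universe = set().union(*feature_sets.values())
    for f in universe:
        key = frozenset(n for n in names if f in feature_sets[n])
        counts[key] += 1
    return IntersectionCounts(
        counts=counts, set_sizes={n: len(feature_sets[n]) for n in names}
    )


def plot_upset(counts: IntersectionCounts, path: str | Path) -> None:
    """Minimal UpSet-style figure (bar panel + membership dot matrix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = counts.to_frame()
    df = df[df["count"] > 0].sort_values("count", ascending=False).reset_index(drop=True)
    names = sorted(counts.set_sizes)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(6, 0.5 * len(df) + 2), 5), sharex=True,
        gridspec_kw={"height_ratios": [3, 1]},
    )
    ax_bar.bar(range(len(df)), df["count"], color="0.3")
    ax_bar.set_ylabel("exclusive feature count")
    for x, combo in enumerate(df["combination"]):
        present = set(combo.split("&"))
        for y, name in enumerate(names):
            ax_dot.plot(x, y, "o", color="0.2" if name in present else "0.85", ms=8)
    ax_dot.set_yticks(range(len(names)), names)
    ax_dot.set_xticks([])
    ax_dot.set_ylim(-0.5, len(names) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
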
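"""Peak-list handling and cross-sample feature alignment for untargeted LC-MS.

A *peak* is an (m/z, retention time, abundance) triple measured in one
sample; a *feature* is a group of peaks, at most one per sample, that fall
within the instrument's mass tolerance (ppm) and retention-time window and
are therefore treated as the same analyte signal across samples.

Alignment here is greedy centroid clustering: peaks are visited in
descending abundance order and either join the nearest existing feature
(consensus m/z and RT are abundance-weighted means of the members) or seed a
new one.  Defaults follow common TOF practice: 15 ppm mass error, 0.15 min
RT shift, and a 200-count noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "FeatureTable",
    "PeakListError",
    "read_peak_lists",
    "write_peak_lists",
    "noise_filter",
    "align_features",
    "annotate_adduct_groups",
    "write_feature_table",
    "read_feature_table",
    "ADDUCT_OFFSETS",
]

SAMPLE_ROLES = ("study", "blank", "qc")

PEAK_COLUMNS = ["mz", "rt", "abundance"]
METADATA_COLUMNS = ["sample_id", "role", "method", "replicate", "design_run", "injection_order"]


class PeakListError(ValueError):
    """Malformed peak-list or metadata input (carries file/line context)."""


@dataclass
class PeakList:
    """All peaks of one injection plus its sample metadata."""

    sample_id: str
    role: str = "study"
    method: str | None = None
    replicate: int | None = None
    design_run: str | None = None
    injection_order: int | None = None
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise ValueError(f"sample {self.sample_id!r}: unknown role {self.role!r}")
        self.peaks = self.peaks.reset_index(drop=True)[PEAK_COLUMNS].astype(float)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def metadata(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "role": self.role,
            "method": self.method,
            "replicate": self.replicate,
            "design_run": self.design_run,
            "injection_order": self.injection_order,
        }


@dataclass
class FeatureTable:
    """Aligned features x samples abundance matrix.

    ``features`` is indexed by feature id with columns ``mz``, ``rt`` and
    (after annotation) ``adduct_group``; ``abundance`` shares that index with
    one column per sample, missing values as NaN (never zero); ``samples``
    is indexed by sample id and carries the roles and group labels.
    """

    features: pd.DataFrame
    abundance: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.abundance.index):
            raise ValueError("features and abundance must share a feature index")
        missing = [s for s in self.abundance.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.abundance.columns if self.samples.loc[s, "role"] == role]

    def subset_features(self, feature_ids: Iterable) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            features=self.features.loc[ids].copy(),
            abundance=self.abundance.loc[ids].copy(),
            samples=self.samples.copy(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            features=self.features.copy(),
            abundance=self.abundance[ids].copy(),
            samples=self.samples.loc[ids].copy(),
        )


# ---------------------------------------------------------------------------
# I/O


def _read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str, "design_run": str})
    missing = [c for c in ("sample_id", "role") if c not in meta.columns]
    if missing:
        raise PeakListError(f"{metadata_path}: metadata lacks columns {missing}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
    if dup:
        raise PeakListError(f"{metadata_path}: duplicate sample ids {sorted(set(dup))}")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = None
    return meta.set_index("sample_id", drop=False)


def read_peak_lists(peaks_path: str | Path, metadata_path: str | Path) -> list[PeakList]:
    """Read a long-format peak CSV (sample_id, mz, rt, abundance) plus metadata.

    Every sample in the peak file must appear in the metadata; malformed
    rows are rejected with their file and line number.
    """
    meta = _read_metadata(metadata_path)
    df = pd.read_csv(peaks_path, dtype={"sample_id": str})
    need = ["sample_id", *PEAK_COLUMNS]
    lacking = [c for c in need if c not in df.columns]
    if lacking:
        raise PeakListError(f"{peaks_path}: peak file lacks columns {lacking}")
    # +2: header line and 1-based numbering
    bad = df.index[(df["mz"] <= 0) | df["mz"].isna()]
    if len(bad):
        raise PeakListError(f"{peaks_path}: line {bad[0] + 2}: non-positive or missing mz")
    bad = df.index[(df["abundance"] < 0) | df["abundance"].isna()]
    if len(bad):
        raise PeakListError(f"{peaks_path}: line {bad[0] + 2}: negative or missing abundance")
    bad = df.index[(df["rt"] < 0) | df["rt"].isna()]
    if len(bad):
        raise PeakListError(f"{peaks_path}: line {bad[0] + 2}: negative or missing rt")
    unknown = sorted(set(df["sample_id"]) - set(meta.index))
    if unknown:
        raise PeakListError(f"{metadata_path}: metadata missing sample ids {unknown}")
    out = []
    for sid, rec in meta.iterrows():
        peaks = df.loc[df["sample_id"] == sid, PEAK_COLUMNS]
        out.append(
            PeakList(
                sample_id=sid,
                role=rec["role"],
                method=None if pd.isna(rec["method"]) else rec["method"],
                replicate=None if pd.isna(rec["replicate"]) else int(rec["replicate"]),
                design_run=None if pd.isna(rec["design_run"]) else str(rec["design_run"]),
                injection_order=None
                if pd.isna(rec["injection_order"])
                else int(rec["injection_order"]),
                peaks=peaks,
            )
        )
    return out


def write_peak_lists(
    peaklists: Sequence[PeakList], peaks_path: str | Path, metadata_path: str | Path
) -> None:
    """Write peak lists in the long CSV dialect that :func:`read_peak_lists` reads."""
    frames = []
    for pl in peaklists:
        df = pl.peaks.copy()
        df.insert(0, "sample_id", pl.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(peaks_path, index=False)
    pd.DataFrame([pl.metadata for pl in peaklists]).to_csv(metadata_path, index=False)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Feature CSV: feature_id, mz, rt[, adduct_group], one column per sample.

    Missing abundances are written as empty cells, keeping the distinction
    between "not detected" and zero signal.
    """
    df = table.features.copy()
    df.insert(0, "feature_id", df.index)
    out = pd.concat([df.reset_index(drop=True), table.abundance.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path, metadata_path: str | Path | None = None) -> FeatureTable:
    df = pd.read_csv(path)
    feat_cols = [c for c in ("feature_id", "mz", "rt", "adduct_group") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in feat_cols]
    features = df[feat_cols].set_index("feature_id")
    abundance = df[sample_cols].copy()
    abundance.index = features.index
    if metadata_path is not None:
        samples = _read_metadata(metadata_path).loc[sample_cols]
    else:
        samples = pd.DataFrame(
            {"sample_id": sample_cols, "role": "study"}, index=pd.Index(sample_cols)
        )
        for col in METADATA_COLUMNS:
            if col not in samples.columns:
                samples[col] = None
    return FeatureTable(features=features, abundance=abundance, samples=samples)


# ---------------------------------------------------------------------------
# Noise filtering


def noise_filter(peaklist: PeakList, threshold: float = 200.0) -> PeakList:
    """Drop peaks whose abundance is strictly below ``threshold`` counts.

    Signals lower than the floor are treated as background noise; a peak at
    exactly the threshold is retained.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = peaklist.peaks[peaklist.peaks["abundance"] >= threshold]
    return replace(peaklist, peaks=kept.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Alignment


def align_features(
    peaklists: Sequence[PeakList],
    ppm_tol: float = 15.0,
    rt_tol_min: float = 0.15,
) -> FeatureTable:
    """Group peaks across samples into features under ppm and RT tolerances.

    Peaks are processed in descending abundance (ties broken on m/z, RT and
    sample id so the result is deterministic).  A peak may join a feature iff
    its m/z is within ``ppm_tol`` parts-per-million of the feature's
    consensus m/z and its RT within ``rt_tol_min`` minutes of the consensus
    RT, and the feature holds no peak from the same sample yet.  Among
    admissible features the smallest ppm distance wins (then smallest RT
    distance, then lowest feature id); otherwise the peak seeds a new
    feature.  Consensus m/z and RT are abundance-weighted means of members.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    if ppm_tol <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be positive")
    ids = [pl.sample_id for pl in peaklists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in peak lists")

    rows = []
    for si, pl in enumerate(sorted(peaklists, key=lambda p: p.sample_id)):
        for mz, rt, ab in pl.peaks.itertuples(index=False):
            rows.append((float(ab), float(mz), float(rt), si))
    order = sorted(range(len(rows)), key=lambda i: (-rows[i][0], rows[i][1], rows[i][2], rows[i][3]))

    cap = max(len(rows), 1)
    cons_mz = np.empty(cap)
    cons_rt = np.empty(cap)
    wsum = np.empty(cap)
    n_feat = 0
    members: list[list[tuple[int, float, float, float]]] = []  # (sample, mz, rt, ab)
    sample_sets: list[set[int]] = []

    for i in order:
        ab, mz, rt, si = rows[i]
        best = -1
        if n_feat:
            dmz = np.abs(cons_mz[:n_feat] - mz)
            ppm = dmz / cons_mz[:n_feat] * 1e6
            drt = np.abs(cons_rt[:n_feat] - rt)
            ok = (ppm <= ppm_tol) & (drt <= rt_tol_min)
            if ok.any():
                cand = np.flatnonzero(ok)
                cand = np.array([f for f in cand if si not in sample_sets[f]], dtype=int)
                if cand.size:
                    key = np.lexsort((cand, drt[cand], ppm[cand]))
                    best = int(cand[key[0]])
        if best < 0:
            best = n_feat
            n_feat += 1
            cons_mz[best] = mz
            cons_rt[best] = rt
            wsum[best] = 0.0
            members.append([])
            sample_sets.append(set())
        w = max(ab, 1e-12)  # zero-abundance peaks still need a location
        tot = wsum[best] + w
        cons_mz[best] = (cons_mz[best] * wsum[best] + mz * w) / tot
        cons_rt[best] = (cons_rt[best] * wsum[best] + rt * w) / tot
        wsum[best] = tot
        members[best].append((si, mz, rt, ab))
        sample_sets[best].add(si)

    sorted_pls = sorted(peaklists, key=lambda p: p.sample_id)
    sample_ids = [pl.sample_id for pl in sorted_pls]
    # stable feature ids: ordered by consensus (rt, mz)
    feat_order = sorted(range(n_feat), key=lambda f: (cons_rt[f], cons_mz[f]))
    fids = [f"F{k + 1:05d}" for k in range(n_feat)]
    mat = np.full((n_feat, len(sample_ids)), np.nan)
    for k, f in enumerate(feat_order):
        for si, _mz, _rt, ab in members[f]:
            mat[k, si] = ab
    features = pd.DataFrame(
        {
            "mz": [cons_mz[f] for f in feat_order],
            "rt": [cons_rt[f] for f in feat_order],
            "adduct_group": pd.array([pd.NA] * n_feat, dtype="Int64"),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    abundance = pd.DataFrame(mat, index=features.index, columns=sample_ids)
    samples = pd.DataFrame([pl.metadata for pl in sorted_pls]).set_index("sample_id", drop=False)
    return FeatureTable(features=features, abundance=abundance, samples=samples)


# ---------------------------------------------------------------------------
# Adduct grouping

_E = 0.000548579909  # electron mass, Da
_H = 1.00782503207
_H2O = 18.0105646863
_NA = 22.9897692809
_K = 38.96370649
_N = 14.0030740048
_CL = 34.96885268
_O = 15.9949146196
_C = 12.0

# Ion m/z offset relative to the neutral molecule M, per ionization mode.
ADDUCT_OFFSETS: dict[str, dict[str, float]] = {
    "positive": {
        "[M+H]+": _H - _E,
        "[M+Na]+": _NA - _E,
        "[M+K]+": _K - _E,
        "[M+NH4]+": _N + 4 * _H - _E,
        "[M+H-H2O]+": _H - _E - _H2O,
    },
    "negative": {
        "[M-H]-": -(_H - _E),
        "[M+HCOO]-": _C + _H + 2 * _O + _E,
        "[M+Cl]-": _CL + _E,
        "[M-H-H2O]-": -(_H - _E) - _H2O,
    },
}


def annotate_adduct_groups(
    table: FeatureTable,
    mode: str,
    ppm_tol: float = 15.0,
    rt_tol_min: float = 0.15,
) -> FeatureTable:
    """Group co-eluting features whose m/z gaps match adduct/neutral-loss deltas.

    Two features are linked when their consensus RTs differ by at most
    ``rt_tol_min`` and their m/z difference matches (within ``ppm_tol`` of
    the larger m/z) some pairwise difference of the mode's adduct offsets;
    groups are the transitive closure of these links.  Annotation is
    informational — abundances are never merged.
    """
    if mode not in ADDUCT_OFFSETS:
        raise ValueError(f"mode must be one of {sorted(ADDUCT_OFFSETS)}, got {mode!r}")
    offs = sorted(ADDUCT_OFFSETS[mode].values())
    deltas = sorted({abs(a - b) for a in offs for b in offs if abs(a - b) > 1e-9})

    mz = table.features["mz"].to_numpy(float)
    rt = table.features["rt"].to_numpy(float)
    n = len(mz)
    order = np.argsort(mz)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    mz_sorted = mz[order]
    for delta in deltas:
        for pos, i in enumerate(order):
            target = mz[i] + delta
            tol = ppm_tol * 1e-6 * target
            lo = np.searchsorted(mz_sorted, target - tol, side="left")
            hi = np.searchsorted(mz_sorted, target + tol, side="right")
            for j in order[lo:hi]:
                if j != i and abs(rt[j] - rt[i]) <= rt_tol_min:
                    union(int(i), int(j))

    roots = [find(i) for i in range(n)]
    gid = {r: k + 1 for k, r in enumerate(sorted(set(roots), key=lambda r: roots.index(r)))}
    features = table.features.copy()
    features["adduct_group"] = pd.array([gid[r] for r in roots], dtype="Int64")
    return FeatureTable(features=features, abundance=table.abundance.copy(), samples=table.samples.copy())
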
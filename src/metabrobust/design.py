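"""Plackett-Burman screening designs for analytical-method robustness testing.

A Plackett-Burman (PB) design screens up to ``n - 1`` factors in ``n`` runs,
where ``n`` is a multiple of 4.  Every factor is set at two coded levels
(-1 and +1); centre-point runs (all factors at their coded-0 midpoint) may be
replicated to gauge measurement uncertainty.  PB designs estimate main
effects only — all interactions are assumed negligible — which makes them the
standard choice for robustness screening, where many small deliberate
perturbations of a protocol are tested at once.

This module builds the coded matrices by cyclic rotation of the classical
generating rows, validates the defining balance/orthogonality properties,
and maps coded runs to physical worksheets (µL, min, °C) and back.  A dummy
factor — a column tied to no physical change — can be carried along; its
apparent effect estimates experimental error.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FactorSpec",
    "DesignRun",
    "DesignMatrix",
    "DesignValidationReport",
    "UnsupportedDesignSizeError",
    "generate_pb_matrix",
    "add_centre_points",
    "decode_run",
    "encode_run",
    "validate_design",
    "read_design_csv",
    "write_design_csv",
    "write_worksheet_csv",
    "load_table1_design",
]

# Classical cyclic generating rows (first rows); the full factorial design is
# the n-1 cyclic rotations of the generator plus one all-minus row.
PB_GENERATORS: dict[int, str] = {
    4: "++-",
    8: "+++-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
}

_LEVEL_TO_CHAR = {-1: "-", 0: "0", 1: "+"}
# accept both the unicode minus sign and the ascii hyphen on input
_CHAR_TO_LEVEL = {"-": -1, "−": -1, "0": 0, "+": 1}


class UnsupportedDesignSizeError(ValueError):
    """Raised when no generating row is known for the requested run count."""


@dataclass(frozen=True)
class FactorSpec:
    """Physical meaning of one design factor.

    Parameters
    ----------
    name:
        Short label, e.g. ``"MTBE2"``.
    units:
        Free text (``"µL"``, ``"min"``, ``"°C"``); empty for dummy factors.
    low, centre, high:
        Physical values at coded -1, 0 and +1.  Strictly ordered for real
        factors.
    is_dummy:
        Dummy factors carry no physical change; they decode to their coded
        value and serve as an error estimate in the analysis.
    """

    name: str
    low: float
    centre: float
    high: float
    units: str = ""
    is_dummy: bool = False

    def __post_init__(self) -> None:
        if self.is_dummy:
            if self.units:
                raise ValueError(f"dummy factor {self.name!r} must not have units")
        elif not (self.low < self.centre < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < centre < high, "
                f"got {self.low}, {self.centre}, {self.high}"
            )

    def decode(self, level: int) -> float:
        """Map a coded level in {-1, 0, +1} to its physical value."""
        if self.is_dummy:
            if level not in (-1, 0, 1):
                raise ValueError(f"coded level {level!r} outside {{-1, 0, +1}}")
            return float(level)
        try:
            return {-1: self.low, 0: self.centre, 1: self.high}[level]
        except KeyError:
            raise ValueError(f"coded level {level!r} outside {{-1, 0, +1}}") from None

    def encode(self, value: float) -> int:
        """Inverse of :meth:`decode`; the physical value must match a level."""
        for level in (-1, 0, 1):
            if self.decode(level) == value:
                return level
        raise ValueError(f"value {value!r} matches no level of factor {self.name!r}")


@dataclass(frozen=True)
class DesignRun:
    """One run of a design: identifier, pattern string and coded levels."""

    run_id: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = [lv for lv in self.levels if lv not in (-1, 0, 1)]
        if bad:
            raise ValueError(f"run {self.run_id!r}: coded levels outside {{-1,0,+1}}: {bad}")

    @property
    def is_centre(self) -> bool:
        return all(lv == 0 for lv in self.levels)

    @property
    def pattern(self) -> str:
        """Pattern string; centre runs collapse to ``"0"`` as printed in worksheets."""
        if self.is_centre:
            return "0"
        return "".join(_LEVEL_TO_CHAR[lv] for lv in self.levels)


def _parse_pattern(pattern: str, n_factors: int) -> tuple[int, ...]:
    pattern = pattern.strip()
    if pattern == "0":
        return (0,) * n_factors
    if len(pattern) != n_factors:
        raise ValueError(
            f"pattern {pattern!r} has length {len(pattern)}, expected {n_factors}"
        )
    try:
        return tuple(_CHAR_TO_LEVEL[c] for c in pattern)
    except KeyError as exc:
        raise ValueError(f"pattern {pattern!r}: unknown symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class DesignMatrix:
    """Ordered runs x factors, coded in {-1, 0, +1}."""

    runs: tuple[DesignRun, ...]
    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        n = len(self.factors)
        for run in self.runs:
            if len(run.levels) != n:
                raise ValueError(
                    f"run {run.run_id!r} has {len(run.levels)} levels for {n} factors"
                )
            if not run.is_centre and any(lv == 0 for lv in run.levels):
                raise ValueError(
                    f"run {run.run_id!r} mixes 0 with factorial levels; runs must be "
                    "fully factorial or fully centre"
                )

    @property
    def factorial_runs(self) -> tuple[DesignRun, ...]:
        return tuple(r for r in self.runs if not r.is_centre)

    @property
    def centre_runs(self) -> tuple[DesignRun, ...]:
        return tuple(r for r in self.runs if r.is_centre)

    @property
    def n_factorial(self) -> int:
        return len(self.factorial_runs)

    @property
    def n_centre(self) -> int:
        return len(self.centre_runs)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def coded_array(self, factorial_only: bool = False):
        import numpy as np

        runs = self.factorial_runs if factorial_only else self.runs
        return np.array([r.levels for r in runs], dtype=int)

    def run(self, run_id: str) -> DesignRun:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(f"no run with id {run_id!r}")

    def randomized(self, seed: int) -> "DesignMatrix":
        """Return a copy with execution order shuffled (off by default everywhere)."""
        order = list(self.runs)
        random.Random(seed).shuffle(order)
        return DesignMatrix(runs=tuple(order), factors=self.factors)


@dataclass
class DesignValidationReport:
    """Per-factor balance flags and per-pair orthogonality flags."""

    balanced: dict[str, bool]
    orthogonal: dict[tuple[str, str], bool]
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(self.balanced.values()) and all(self.orthogonal.values())


def generate_pb_matrix(
    n_factors: int,
    seed_row: int | None = None,
    factors: Sequence[FactorSpec] | None = None,
) -> DesignMatrix:
    """Build a factorial-only Plackett-Burman design for ``n_factors`` factors.

    The run count is the smallest multiple of 4 strictly greater than
    ``n_factors``.  Rows are the cyclic rotations of the classical generating
    row plus an all-minus row, truncated to ``n_factors`` columns.

    Parameters
    ----------
    seed_row:
        Optional starting rotation of the generating row (a permutation
        choice; any value yields an equivalent design).
    factors:
        Optional physical factor specifications; defaults to generic coded
        placeholders named F1..Fk.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    n_runs = ((n_factors // 4) + 1) * 4
    if n_runs not in PB_GENERATORS:
        raise UnsupportedDesignSizeError(
            f"{n_factors} factors need {n_runs} runs; largest supported generator "
            f"is {max(PB_GENERATORS)} runs"
        )
    gen = [_CHAR_TO_LEVEL[c] for c in PB_GENERATORS[n_runs]]
    width = n_runs - 1
    offset = (seed_row or 0) % width
    rows = []
    for i in range(width):
        shift = (i + offset) % width
        row = tuple(gen[(j + shift) % width] for j in range(width))
        rows.append(row[:n_factors])
    rows.append((-1,) * n_factors)
    if factors is None:
        factors = [
            FactorSpec(name=f"F{j + 1}", low=-1.0, centre=0.0, high=1.0)
            for j in range(n_factors)
        ]
    runs = tuple(
        DesignRun(run_id=str(i + 1), levels=row) for i, row in enumerate(rows)
    )
    return DesignMatrix(runs=runs, factors=tuple(factors))


def _interleaved_positions(n_factorial: int, k: int) -> list[int]:
    # Canonical 15-run worksheet layout: centre runs at ordinal rows 6/10/15.
    # No even-spacing formula reproduces it (factorial blocks of 5/3/4), so the
    # canonical case is pinned and other shapes fall back to even spacing with
    # the last centre closing the batch.
    if n_factorial == 12 and k == 3:
        return [6, 10, 15]
    n_total = n_factorial + k
    return sorted({round(j * n_total / k) for j in range(1, k + 1)})


def add_centre_points(
    design: DesignMatrix,
    k: int,
    placement: str | Sequence[int] = "interleaved",
) -> DesignMatrix:
    """Insert ``k`` centre-point runs (all coded levels 0) into a design.

    ``placement`` is either a policy name — ``"interleaved"`` (default,
    matching the canonical worksheet layout) or ``"append"`` — or an explicit
    sequence of 1-based ordinal positions in the final run order.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return design
    n_total = design.n_factorial + design.n_centre + k
    if isinstance(placement, str):
        if placement == "interleaved":
            positions = _interleaved_positions(design.n_factorial + design.n_centre, k)
        elif placement == "append":
            positions = list(range(n_total - k + 1, n_total + 1))
        else:
            raise ValueError(f"unknown placement policy {placement!r}")
    else:
        positions = sorted(int(p) for p in placement)
        if len(positions) != k:
            raise ValueError(f"{k} centre points but {len(positions)} positions given")
        if positions[0] < 1 or positions[-1] > n_total:
            raise ValueError(f"positions out of range 1..{n_total}")

    n_factors = len(design.factors)
    existing = iter(design.runs)
    centre_positions = set(positions)
    runs: list[DesignRun] = []
    c = 0
    for pos in range(1, n_total + 1):
        if pos in centre_positions:
            c += 1
            runs.append(DesignRun(run_id=f"C{design.n_centre + c}", levels=(0,) * n_factors))
        else:
            runs.append(next(existing))
    return DesignMatrix(runs=tuple(runs), factors=design.factors)


def decode_run(
    run: DesignRun | Sequence[int], factors: Sequence[FactorSpec]
) -> dict[str, float]:
    """Map one coded run to physical factor settings (factor name -> value)."""
    levels = run.levels if isinstance(run, DesignRun) else tuple(run)
    if len(levels) != len(factors):
        raise ValueError(f"{len(levels)} levels for {len(factors)} factors")
    return {f.name: f.decode(lv) for f, lv in zip(factors, levels)}


def encode_run(
    physical: Mapping[str, float], factors: Sequence[FactorSpec]
) -> tuple[int, ...]:
    """Inverse of :func:`decode_run`: physical values back to coded levels."""
    missing = [f.name for f in factors if f.name not in physical]
    if missing:
        raise ValueError(f"missing factors in physical run: {missing}")
    return tuple(f.encode(physical[f.name]) for f in factors)


def validate_design(design: DesignMatrix) -> DesignValidationReport:
    """Check the defining PB properties over the factorial runs.

    Balance: each coded column has equal counts of -1 and +1.  Orthogonality:
    every pair of coded columns has zero dot product.  Centre runs are
    ignored (they contribute 0 to both checks by construction).
    """
    if not design.runs:
        raise ValueError("design has no runs")
    import numpy as np

    names = design.factor_names
    messages: list[str] = []
    factorial = design.factorial_runs
    if not factorial:
        messages.append("design contains only centre runs; checks are vacuous")
        return DesignValidationReport(
            balanced={n: True for n in names},
            orthogonal={
                (names[i], names[j]): True
                for i in range(len(names))
                for j in range(i + 1, len(names))
            },
            messages=messages,
        )
    X = np.array([r.levels for r in factorial], dtype=int)
    balanced = {}
    for j, name in enumerate(names):
        ok = int(X[:, j].sum()) == 0
        balanced[name] = ok
        if not ok:
            messages.append(f"column {name!r} unbalanced (sum {int(X[:, j].sum())})")
    orthogonal = {}
    G = X.T @ X
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ok = int(G[i, j]) == 0
            orthogonal[(names[i], names[j])] = ok
            if not ok:
                messages.append(
                    f"columns {names[i]!r} and {names[j]!r} not orthogonal "
                    f"(dot product {int(G[i, j])})"
                )
    if design.n_factorial % 4 != 0:
        messages.append(
            f"factorial run count {design.n_factorial} is not a multiple of 4"
        )
    return DesignValidationReport(balanced=balanced, orthogonal=orthogonal, messages=messages)


# ---------------------------------------------------------------------------
# I/O


def write_design_csv(design: DesignMatrix, path: str | Path) -> None:
    """Write the coded matrix: run id, pattern, one integer column per factor."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run", "pattern", *design.factor_names])
        for r in design.runs:
            w.writerow([r.run_id, r.pattern, *r.levels])


def read_design_csv(
    path: str | Path, factors: Sequence[FactorSpec] | None = None
) -> DesignMatrix:
    """Read a coded design written by :func:`write_design_csv`.

    Lines starting with ``#`` are comments.  The pattern column is
    cross-checked against the coded columns.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    header = rows[0]
    if header[:2] != ["run", "pattern"]:
        raise ValueError(f"{path}: expected header starting 'run,pattern', got {header[:2]}")
    names = header[2:]
    if factors is None:
        factors = [FactorSpec(name=n, low=-1.0, centre=0.0, high=1.0) for n in names]
    elif list(names) != [f.name for f in factors]:
        raise ValueError(f"{path}: factor columns {names} do not match provided specs")
    runs = []
    for row in rows[1:]:
        run_id, pattern, *levels = row
        coded = tuple(int(v) for v in levels)
        if _parse_pattern(pattern, len(names)) != coded:
            raise ValueError(f"{path}: run {run_id!r}: pattern disagrees with coded levels")
        runs.append(DesignRun(run_id=run_id, levels=coded))
    return DesignMatrix(runs=tuple(runs), factors=tuple(factors))


def write_worksheet_csv(design: DesignMatrix, path: str | Path) -> None:
    """Write the decoded physical worksheet (one column per factor, in units)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        headers = [
            f"{f.name} [{f.units}]" if f.units else f.name for f in design.factors
        ]
        w.writerow(["run", "pattern", *headers])
        for r in design.runs:
            phys = decode_run(r, design.factors)
            w.writerow([r.run_id, r.pattern, *[phys[f.name] for f in design.factors]])


_DATA_DIR = Path(__file__).parent / "data"


def load_table1_design() -> DesignMatrix:
    """Load the packaged 15-run worksheet (10 physical factors + dummy, 3 centre runs).

    The fixture is transcribed from the published robustness worksheet; the
    physical values are encoded back to coded levels via each factor's
    low/centre/high.
    """
    factors = _read_factor_specs(_DATA_DIR / "table1_factors.csv")
    by_name = {f.name: f for f in factors}
    with open(_DATA_DIR / "table1_design.csv", newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    header = rows[0]
    names = header[2:]
    runs = []
    for row in rows[1:]:
        run_id, pattern, *values = row
        coded = tuple(by_name[n].encode(float(v)) for n, v in zip(names, values))
        if _parse_pattern(pattern, len(names)) != coded:
            raise ValueError(f"table1 fixture: run {run_id!r} pattern/value mismatch")
        runs.append(DesignRun(run_id=run_id, levels=coded))
    return DesignMatrix(runs=tuple(runs), factors=tuple(factors))


def _read_factor_specs(path: str | Path) -> tuple[FactorSpec, ...]:
    with open(path, newline="") as fh:
        text = "".join(ln for ln in fh if not ln.lstrip().startswith("#"))
    out = []
    for rec in csv.DictReader(io.StringIO(text)):
        out.append(
            FactorSpec(
                name=rec["name"],
                units=rec["units"],
                low=float(rec["low"]),
                centre=float(rec["centre"]),
                high=float(rec["high"]),
                is_dummy=rec["is_dummy"].strip().lower() in ("1", "true", "yes"),
            )
        )
    return tuple(out)


def read_factor_specs(path: str | Path) -> tuple[FactorSpec, ...]:
    """Read factor specifications (name, units, low, centre, high, is_dummy) from CSV."""
    return _read_factor_specs(path)
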
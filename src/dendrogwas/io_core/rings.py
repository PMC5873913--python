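"""Tree-ring series data model plus Tucson (.rwl) and long-form CSV readers/writers.

A :class:`RingSeries` holds per-year wood measurements for one core (or a
core-averaged tree): ring width ``RW``, earlywood/latewood widths ``EW``/``LW``
(mm), latewood proportion ``LWP`` (%), and the densities ``RD``, ``ED``, ``LD``,
``MIND``, ``MAXD`` (kg/m3).  Missing values are explicit NaNs, never silent
zeros, because the drought-window rules need to distinguish "no ring measured"
from "zero growth".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .log import get_logger

log = get_logger("io.rings")

#: Measurement column order used by the long-form CSV schema.
MEASUREMENTS = ("RW", "EW", "LW", "LWP", "RD", "ED", "LD", "MIND", "MAXD")

LONG_CSV_COLUMNS = ("tree_id", "core_id", "provenance", "year") + MEASUREMENTS

#: EW + LW must equal RW within this tolerance (mm) when all three are present.
EW_LW_TOL = 1e-6


class RingFormatError(ValueError):
    """Malformed ring-series file."""


@dataclass
class RingSeries:
    """Annual wood measurements for one core of one tree.

    ``years`` is strictly increasing with no duplicates; ``data`` maps each
    measurement name to a float array aligned with ``years`` (NaN = missing).
    """

    tree_id: str
    core_id: str
    provenance: str
    years: np.ndarray
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise RingFormatError(
                f"series {self.tree_id}/{self.core_id}: years not strictly increasing"
            )
        for name in MEASUREMENTS:
            if name in self.data:
                arr = np.asarray(self.data[name], dtype=float)
                if arr.shape != self.years.shape:
                    raise RingFormatError(
                        f"series {self.tree_id}/{self.core_id}: {name} length mismatch"
                    )
                self.data[name] = arr

    @property
    def rw(self) -> np.ndarray:
        return self.data["RW"]

    def value(self, measurement: str, year: int) -> float:
        """Measurement value at ``year`` (NaN when the year or value is absent)."""
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0 or measurement not in self.data:
            return float("nan")
        return float(self.data[measurement][idx[0]])

    def validate(self) -> list[str]:
        """Check invariants; returns warning messages (logged, non-fatal)."""
        warnings: list[str] = []
        tag = f"{self.tree_id}/{self.core_id}"
        d = self.data
        if "RW" in d and np.any(d["RW"][~np.isnan(d["RW"])] < 0):
            warnings.append(f"{tag}: negative RW")
        if "RW" in d and "EW" in d and "LW" in d:
            mask = ~(np.isnan(d["RW"]) | np.isnan(d["EW"]) | np.isnan(d["LW"]))
            bad = np.abs(d["EW"][mask] + d["LW"][mask] - d["RW"][mask]) > EW_LW_TOL
            if np.any(bad):
                years = self.years[mask][bad]
                warnings.append(f"{tag}: EW+LW != RW in years {years.tolist()}")
        if "LWP" in d:
            v = d["LWP"][~np.isnan(d["LWP"])]
            if np.any((v < 0) | (v > 100)):
                warnings.append(f"{tag}: LWP outside [0, 100]")
        if all(k in d for k in ("MIND", "RD", "MAXD")):
            mask = ~(np.isnan(d["MIND"]) | np.isnan(d["RD"]) | np.isnan(d["MAXD"]))
            if np.any(d["MIND"][mask] > d["RD"][mask]) or np.any(
                d["RD"][mask] > d["MAXD"][mask]
            ):
                warnings.append(f"{tag}: density ordering MIND <= RD <= MAXD violated")
        for w in warnings:
            log.warning(w)
        return warnings


# ---------------------------------------------------------------------------
# Tucson decadal (.rwl)
# ---------------------------------------------------------------------------

_TERMINATORS = {999: 0.01, -9999: 0.001}


def read_rwl(path) -> dict[str, RingSeries]:
    """Read a Tucson decadal-format file into RW-only series keyed by series id.

    Terminator ``999`` marks 0.01 mm units, ``-9999`` marks 0.001 mm; values
    are converted to mm and the terminator row is excluded.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    done: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise RingFormatError(f"{path}: malformed decade line {lineno}")
            try:
                decade_year = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RingFormatError(f"{path}: malformed decade line {lineno}") from exc
            if sid in done:
                raise RingFormatError(
                    f"{path}: line {lineno}: data for {sid!r} after its terminator"
                )
            series = raw.setdefault(sid, [])
            if sid not in order:
                order.append(sid)
            year = decade_year
            for v in vals:
                if v in _TERMINATORS:
                    done[sid] = _TERMINATORS[v]
                    break
                series.append((year, v))
                year += 1
    out: dict[str, RingSeries] = {}
    for sid in order:
        if sid not in done:
            raise RingFormatError(f"{path}: series {sid!r} has no terminator")
        scale = done[sid]
        years = np.array([y for y, _ in raw[sid]], dtype=int)
        vals = np.array([v for _, v in raw[sid]], dtype=float) * scale
        out[sid] = RingSeries(
            tree_id=sid, core_id=sid, provenance="", years=years, data={"RW": vals}
        )
    return out


def write_rwl(series: dict[str, RingSeries], path, units: float = 0.001) -> None:
    """Write RW series in Tucson decadal format.

    ``units`` is the storage precision in mm: 0.001 (terminator -9999, the
    default, lossless for 3-decimal data) or 0.01 (terminator 999).
    """
    if units == 0.001:
        terminator = -9999
    elif units == 0.01:
        terminator = 999
    else:
        raise ValueError("units must be 0.001 or 0.01 mm")
    with open(path, "w") as fh:
        for sid, s in series.items():
            if len(sid) > 8:
                raise RingFormatError(f"series id {sid!r} longer than 8 characters")
            years = s.years
            vals = np.round(s.rw / units).astype(int)
            i = 0
            while i < len(years):
                y = years[i]
                row = [f"{sid:<8s}", f"{y:4d}"]
                while i < len(years) and (years[i] % 10 != 0 or len(row) == 2):
                    row.append(f"{vals[i]:6d}")
                    i += 1
                if i == len(years):
                    row.append(f"{terminator:6d}")
                fh.write("".join(row) + "\n")


# ---------------------------------------------------------------------------
# Long-form CSV (all nine measurements)
# ---------------------------------------------------------------------------


def read_long_csv(path) -> dict[tuple[str, str], RingSeries]:
    """Read long-form ring CSV into series keyed by ``(tree_id, core_id)``.

    Header must contain ``tree_id,core_id,provenance,year`` plus the nine
    measurement columns; empty cells are missing.  RingSeries invariants are
    enforced with warnings for violations beyond tolerance (rows are kept).
    """
    df = pd.read_csv(path, dtype={"tree_id": str, "core_id": str, "provenance": str})
    missing_cols = set(LONG_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise RingFormatError(f"{path}: missing mandatory columns {sorted(missing_cols)}")
    out: dict[tuple[str, str], RingSeries] = {}
    for (tree_id, core_id), grp in df.groupby(["tree_id", "core_id"], sort=False):
        grp = grp.sort_values("year")
        if grp["year"].duplicated().any():
            raise RingFormatError(f"{path}: duplicate years for {tree_id}/{core_id}")
        s = RingSeries(
            tree_id=str(tree_id),
            core_id=str(core_id),
            provenance=str(grp["provenance"].iloc[0]),
            years=grp["year"].to_numpy(dtype=int),
            data={m: grp[m].to_numpy(dtype=float) for m in MEASUREMENTS},
        )
        s.validate()
        out[(str(tree_id), str(core_id))] = s
    return out


def write_long_csv(series, path) -> None:
    """Write series (mapping or iterable of RingSeries) to the long-form CSV."""
    if isinstance(series, dict):
        series = series.values()
    rows = []
    for s in series:
        for i, year in enumerate(s.years):
            row = {
                "tree_id": s.tree_id,
                "core_id": s.core_id,
                "provenance": s.provenance,
                "year": int(year),
            }
            for m in MEASUREMENTS:
                v = s.data[m][i] if m in s.data else np.nan
                row[m] = v
            rows.append(row)
    pd.DataFrame(rows, columns=list(LONG_CSV_COLUMNS)).to_csv(path, index=False)
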
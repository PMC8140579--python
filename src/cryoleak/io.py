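"""Tabular data model and delimited-file I/O.

One tube (stem-segment sample) per row, long format. Conductivities are in
µS/cm; temperatures are the actual values reached during the freeze run (signed
real °C), so unfrozen controls appear as ordinary rows around +4 °C and are
selected by temperature downstream, never by a flag.

All readers accept both the ASCII hyphen-minus and the Unicode minus sign
(U+2212) in numeric fields, since the latter is common in exported tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, TableParseError

CONTROL_TYPES = ("autoclave_120", "boil_100", "liquid_nitrogen", "freeze_minus80")
SERIES_KINDS = ("R", "I", "I_adj", "VD")
QUARTILE_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)

_MINUS_SIGNS = str.maketrans({"−": "-", "–": "-"})


def _parse_float(text: str) -> float:
    return float(str(text).strip().translate(_MINUS_SIGNS))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConductivityRecord:
    """One tube: identifiers, treatment temperature, and its two conductivity reads.

    ``L_T`` is the post-freeze conductivity, ``L_K`` the post-control
    (autoclave / liquid nitrogen / ...) conductivity of the same tube. ``L_K``
    may be absent for datasets read before the control step has been run.
    R = L_T/L_K > 1 is physically odd but is flagged downstream, not rejected
    here.
    """

    species: str
    genotype: str
    replicate: int
    temperature_C: float
    L_T: float
    L_K: float | None = None
    control_type: str = "autoclave_120"
    incubation_days: int | None = None

    def __post_init__(self) -> None:
        if self.L_T < 0:
            raise DomainError(f"L_T must be >= 0, got {self.L_T}")
        if self.L_K is not None and self.L_K <= 0:
            raise DomainError(f"L_K must be > 0 when present, got {self.L_K}")
        if not -210.0 <= self.temperature_C <= 50.0:
            raise DomainError(
                f"temperature_C {self.temperature_C} outside plausible range [-210, 50]"
            )
        if self.control_type not in CONTROL_TYPES:
            raise DomainError(
                f"control_type {self.control_type!r} not one of {CONTROL_TYPES}"
            )
        if self.replicate < 1:
            raise DomainError("replicate must be a positive integer")


@dataclass(frozen=True)
class VisualDamageRecord:
    """One stem segment scored on the quartile browning scale (0/25/50/75/100 %)."""

    species: str
    genotype: str
    replicate: int
    temperature_C: float
    damage_pct: float

    def __post_init__(self) -> None:
        if self.damage_pct not in QUARTILE_LEVELS:
            raise DomainError(
                f"damage_pct must be one of {QUARTILE_LEVELS}, got {self.damage_pct}"
            )


@dataclass(frozen=True)
class DTATrace:
    """A differential-thermal-analysis cooling trace for one genotype cell.

    Time must be strictly increasing; temperature must be (approximately)
    monotone decreasing — transient rises up to ``temp_rise_tol`` °C are
    tolerated because exotherms themselves warm the sample slightly.
    """

    genotype: str
    time_s: np.ndarray
    temperature_C: np.ndarray
    voltage_mV: np.ndarray
    temp_rise_tol: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        temp = np.asarray(self.temperature_C, dtype=float)
        v = np.asarray(self.voltage_mV, dtype=float)
        if not (len(t) == len(temp) == len(v)):
            raise DomainError("time, temperature and voltage must have equal length")
        if len(t) < 2:
            raise DomainError("a DTA trace needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise DomainError("time_s must be strictly increasing")
        if np.any(np.diff(temp) > self.temp_rise_tol):
            raise DomainError(
                f"temperature rises by more than {self.temp_rise_tol} °C; "
                "trace is not a cooling ramp"
            )
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "temperature_C", temp)
        object.__setattr__(self, "voltage_mV", v)

    @property
    def span_C(self) -> float:
        return float(self.temperature_C[0] - self.temperature_C[-1])


@dataclass
class LeakageSeries:
    """Per-genotype (temperature, index value) pairs of one index kind.

    ``kind`` is one of R (fraction), I, I_adj, VD (percent). Points are kept at
    replicate level and ordered warm -> cold. ``flags`` records soft anomalies
    (R > 1, negative I) that were retained rather than clamped.
    """

    species: str
    genotype: str
    kind: str
    temperatures: np.ndarray
    values: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in SERIES_KINDS:
            raise DomainError(f"kind must be one of {SERIES_KINDS}")
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise DomainError("temperatures and values must have equal length")
        order = np.argsort(-t, kind="stable")
        self.temperatures = t[order]
        self.values = v[order]

    @property
    def n_distinct_temperatures(self) -> int:
        return len(np.unique(self.temperatures))

    def fit_eligible(self) -> bool:
        """At least 4 distinct temperatures and a non-constant response."""
        return self.n_distinct_temperatures >= 4 and np.ptp(self.values) > 0


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CONDUCTIVITY_REQUIRED = ("species", "genotype", "replicate", "temperature_C", "L_T_uS")
_VISUAL_REQUIRED = ("species", "genotype", "replicate", "temperature_C", "damage_pct")
_DTA_REQUIRED = ("time_s", "temperature_C", "voltage_mV")


def _load_text_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_conductivity_table(path: str | Path) -> list[ConductivityRecord]:
    """Read a long-format conductivity CSV into records.

    Header: species,genotype,replicate,temperature_C,L_T_uS[,L_K_uS]
    [,control_type][,incubation_days]. ``L_K_uS`` may be absent (column missing
    or cells empty) for pre-control datasets. Any unparseable row aborts with a
    :class:`TableParseError` listing the offending file line numbers.
    """
    df = _load_text_table(path, _CONDUCTIVITY_REQUIRED)
    records: list[ConductivityRecord] = []
    row_errors: dict[int, str] = {}
    has_lk = "L_K_uS" in df.columns
    has_ctrl = "control_type" in df.columns
    has_inc = "incubation_days" in df.columns
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            lk_text = str(row["L_K_uS"]).strip() if has_lk else ""
            inc_text = str(row["incubation_days"]).strip() if has_inc else ""
            rec = ConductivityRecord(
                species=str(row["species"]).strip(),
                genotype=str(row["genotype"]).strip(),
                replicate=int(_parse_float(row["replicate"])),
                temperature_C=_parse_float(row["temperature_C"]),
                L_T=_parse_float(row["L_T_uS"]),
                L_K=_parse_float(lk_text) if lk_text else None,
                control_type=(
                    str(row["control_type"]).strip() if has_ctrl else "autoclave_120"
                ),
                incubation_days=int(_parse_float(inc_text)) if inc_text else None,
            )
            records.append(rec)
        except (ValueError, DomainError) as exc:
            row_errors[line_no] = str(exc)
    if row_errors:
        listing = "; ".join(f"line {n}: {msg}" for n, msg in sorted(row_errors.items()))
        raise TableParseError(
            f"{Path(path).name}: {len(row_errors)} unparseable row(s): {listing}",
            row_errors,
        )
    return records


def read_visual_damage_table(path: str | Path) -> list[VisualDamageRecord]:
    """Read a quartile-scale visual damage CSV (see module docstring for header)."""
    df = _load_text_table(path, _VISUAL_REQUIRED)
    records: list[VisualDamageRecord] = []
    row_errors: dict[int, str] = {}
    for i, row in df.iterrows():
        line_no = int(i) + 2
        try:
            records.append(
                VisualDamageRecord(
                    species=str(row["species"]).strip(),
                    genotype=str(row["genotype"]).strip(),
                    replicate=int(_parse_float(row["replicate"])),
                    temperature_C=_parse_float(row["temperature_C"]),
                    damage_pct=_parse_float(row["damage_pct"]),
                )
            )
        except (ValueError, DomainError) as exc:
            row_errors[line_no] = str(exc)
    if row_errors:
        listing = "; ".join(f"line {n}: {msg}" for n, msg in sorted(row_errors.items()))
        raise TableParseError(
            f"{Path(path).name}: {len(row_errors)} unparseable row(s): {listing}",
            row_errors,
        )
    return records


def read_dta_trace(path: str | Path, genotype: str | None = None) -> DTATrace:
    """Read a 3-column DTA CSV (time_s,temperature_C,voltage_mV) into a trace.

    The trace invariants (strictly increasing time, approximately monotone
    cooling) are enforced by the :class:`DTATrace` constructor.
    """
    df = _load_text_table(path, _DTA_REQUIRED)
    row_errors: dict[int, str] = {}
    cols = {name: np.empty(len(df)) for name in _DTA_REQUIRED}
    for i, row in df.iterrows():
        line_no = int(i) + 2
        try:
            for name in _DTA_REQUIRED:
                cols[name][int(i)] = _parse_float(row[name])
        except ValueError as exc:
            row_errors[line_no] = str(exc)
    if row_errors:
        listing = "; ".join(f"line {n}: {msg}" for n, msg in sorted(row_errors.items()))
        raise TableParseError(
            f"{Path(path).name}: {len(row_errors)} unparseable row(s): {listing}",
            row_errors,
        )
    return DTATrace(
        genotype=genotype if genotype is not None else Path(path).stem,
        time_s=cols["time_s"],
        temperature_C=cols["temperature_C"],
        voltage_mV=cols["voltage_mV"],
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

CRITICAL_VALUE_COLUMNS = ("level", "name", "approach", "metric", "temperature_C")


def write_critical_value_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a critical-value table (level,name,approach,metric,temperature_C) to CSV.

    Values round-trip through :func:`read_critical_value_table` to 6 decimals.
    An empty table produces a header-only file and a warning.
    """
    missing = [c for c in CRITICAL_VALUE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"critical value table missing column(s) {missing}")
    if table.empty:
        warnings.warn("writing an empty critical-value table (header only)")
    table.loc[:, list(CRITICAL_VALUE_COLUMNS)].to_csv(
        path, index=False, float_format="%.6f"
    )


def read_critical_value_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CRITICAL_VALUE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing column(s) {missing}")
    return df


def series_to_frame(series: Iterable[LeakageSeries]) -> pd.DataFrame:
    """Flatten leakage series into a tidy frame (species,genotype,kind,temperature_C,value)."""
    rows = []
    for s in series:
        for t, v in zip(s.temperatures, s.values):
            rows.append(
                {
                    "species": s.species,
                    "genotype": s.genotype,
                    "kind": s.kind,
                    "temperature_C": t,
                    "value": v,
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "genotype", "kind", "temperature_C", "value"]
    )
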
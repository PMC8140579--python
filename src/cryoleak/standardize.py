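"""Convert raw conductivities into the three leakage indices.

The chain is

    R_T   = L_T / L_K                      relative leakage (fraction)
    I_T   = 100 (R_T - R_o) / (1 - R_o)    index of injury (percent)
    I_adj = 100 (R_T - R_o) / (R_max - R_o)  adjusted index (percent)

where R_o is the relative leakage of an unfrozen control (handling damage
counts as 0 %) and R_max the maximum relative leakage observed within a
genotype (the low-temperature plateau counts as 100 % damage). Equivalently,
I_adj = 100 I / I_max with I_max = 100 (R_max - R_o)/(1 - R_o); the two forms
are algebraically identical and the identity is asserted in the test suite.

Anomalous values (R > 1, negative I) are retained and flagged, never silently
clamped: clamping before curve fitting would bias the fitted asymptotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDataError, DomainError
from .io import ConductivityRecord, LeakageSeries

#: Records warmer than this are unfrozen controls (the 4 °C treatment).
UNFROZEN_THRESHOLD_C = 0.0
#: The oak-variant baseline pools 4 °C and -5 °C rows; actual temperatures run
#: ~1.5 °C below target, so -5 °C targets appear near -6.5 °C.
MILD_CONTROL_THRESHOLD_C = -7.5

BASELINE_STRATEGIES = ("mean_unfrozen_4C", "min_of_4C_or_minus5C")
MAXIMUM_STRATEGIES = ("max_temperature_mean", "max_replicate")


@dataclass(frozen=True)
class BaselineSpec:
    """How to pick the per-genotype baseline R_o.

    ``mean_unfrozen_4C``: mean R across unfrozen (T > 0 °C) replicate tubes.
    ``min_of_4C_or_minus5C``: minimum R across tubes at 4 °C or -5 °C — used
    for datasets with single tubes per temperature, where a minimum is the
    only defensible low estimate of handling leakage.
    """

    strategy: str = "mean_unfrozen_4C"

    def __post_init__(self) -> None:
        if self.strategy not in BASELINE_STRATEGIES:
            raise DomainError(f"unknown baseline strategy {self.strategy!r}")


@dataclass(frozen=True)
class MaximumSpec:
    """How to pick the per-genotype maximum R_max.

    ``max_temperature_mean``: maximum over per-temperature replicate means
    (robust to a single leaky tube). ``max_replicate``: maximum single tube,
    matching a literal reading of "maximum measured".
    """

    strategy: str = "max_temperature_mean"

    def __post_init__(self) -> None:
        if self.strategy not in MAXIMUM_STRATEGIES:
            raise DomainError(f"unknown maximum strategy {self.strategy!r}")


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------


def relative_leakage(L_T, L_K):
    """R_T = L_T / L_K. Accepts scalars or arrays; L_K must be positive."""
    L_T = np.asarray(L_T, dtype=float)
    L_K = np.asarray(L_K, dtype=float)
    if np.any(L_K <= 0):
        raise DomainError("L_K must be > 0")
    out = L_T / L_K
    return float(out) if out.ndim == 0 else out


def index_of_injury(R_T, R_o):
    """I_T = 100 (R_T - R_o) / (1 - R_o); zero at the unfrozen control by construction."""
    R_T = np.asarray(R_T, dtype=float)
    if not np.all(np.asarray(R_o) < 1):
        raise DomainError("R_o must be < 1")
    out = 100.0 * (R_T - R_o) / (1.0 - R_o)
    return float(out) if out.ndim == 0 else out


def adjusted_index(R_T, R_o, R_max, genotype: str | None = None):
    """I_adj = 100 (R_T - R_o) / (R_max - R_o); 0 at the baseline, 100 at the plateau."""
    R_T = np.asarray(R_T, dtype=float)
    if not R_max > R_o:
        who = f" for genotype {genotype!r}" if genotype else ""
        raise DegenerateDataError(
            f"R_max ({R_max:.4g}) must exceed R_o ({R_o:.4g}){who}"
        )
    out = 100.0 * (R_T - R_o) / (R_max - R_o)
    return float(out) if out.ndim == 0 else out


def injury_maximum(R_o: float, R_max: float) -> float:
    """I_max = 100 (R_max - R_o)/(1 - R_o), the injury index at the leakage plateau."""
    return float(index_of_injury(R_max, R_o))


# ---------------------------------------------------------------------------
# Per-genotype aggregation
# ---------------------------------------------------------------------------


def baseline_R(temperatures: np.ndarray, R: np.ndarray, spec: BaselineSpec) -> float:
    """Compute R_o for one genotype from its replicate-level R values."""
    temperatures = np.asarray(temperatures, dtype=float)
    R = np.asarray(R, dtype=float)
    if spec.strategy == "mean_unfrozen_4C":
        mask = temperatures > UNFROZEN_THRESHOLD_C
        if not mask.any():
            raise DegenerateDataError("no unfrozen-control records (T > 0 °C)")
        return float(R[mask].mean())
    mask = temperatures >= MILD_CONTROL_THRESHOLD_C
    if not mask.any():
        raise DegenerateDataError("no records at 4 °C or -5 °C for baseline")
    return float(R[mask].min())


def maximum_R(temperatures: np.ndarray, R: np.ndarray, spec: MaximumSpec) -> float:
    """Compute R_max for one genotype from its replicate-level R values."""
    temperatures = np.asarray(temperatures, dtype=float)
    R = np.asarray(R, dtype=float)
    if spec.strategy == "max_replicate":
        return float(R.max())
    means = [R[temperatures == t].mean() for t in np.unique(temperatures)]
    return float(max(means))


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------


def standardize_dataset(
    records: Iterable[ConductivityRecord],
    kind: str,
    baseline: BaselineSpec | None = None,
    maximum: MaximumSpec | None = None,
    *,
    clamp: bool = False,
) -> list[LeakageSeries]:
    """Convert records to per-genotype :class:`LeakageSeries` of the given kind.

    ``kind`` is "R", "I" or "I_adj". Records without L_K are skipped with a
    warning (R cannot be formed). Genotypes lacking the controls a kind needs
    (unfrozen rows for I / I_adj, a plateau exceeding the baseline for I_adj)
    are skipped with a warning naming them. With ``clamp=True``, I and I_adj
    values are clipped to [0, 100] after flagging — off by default because
    clamping biases fitted asymptotes.
    """
    if kind not in ("R", "I", "I_adj"):
        raise DomainError(f"kind must be R, I or I_adj, got {kind!r}")
    baseline = baseline or BaselineSpec()
    maximum = maximum or MaximumSpec()

    groups: dict[tuple[str, str], list[ConductivityRecord]] = {}
    n_no_lk = 0
    for rec in records:
        if rec.L_K is None:
            n_no_lk += 1
            continue
        groups.setdefault((rec.species, rec.genotype), []).append(rec)
    if n_no_lk:
        warnings.warn(f"skipped {n_no_lk} record(s) without post-control conductivity")

    out: list[LeakageSeries] = []
    for (species, genotype), recs in groups.items():
        temps = np.array([r.temperature_C for r in recs])
        R = relative_leakage(
            np.array([r.L_T for r in recs]), np.array([r.L_K for r in recs])
        )
        flags = []
        if np.any(R > 1):
            flags.append(f"R>1 at {int(np.sum(R > 1))} point(s)")
        if kind == "R":
            values = R
        else:
            try:
                R_o = baseline_R(temps, R, baseline)
                if kind == "I":
                    values = index_of_injury(R, R_o)
                else:
                    R_max = maximum_R(temps, R, maximum)
                    values = adjusted_index(R, R_o, R_max, genotype=genotype)
            except DegenerateDataError as exc:
                warnings.warn(f"genotype {genotype!r} skipped: {exc}")
                continue
            if np.any(values < 0):
                flags.append(f"negative index at {int(np.sum(values < 0))} point(s)")
            if clamp:
                values = np.clip(values, 0.0, 100.0)
        series = LeakageSeries(species, genotype, kind, temps, np.asarray(values), flags)
        if not series.fit_eligible():
            series.flags.append("fit-ineligible: <4 distinct temperatures or flat")
            warnings.warn(f"genotype {genotype!r}: series is not fit-eligible")
        out.append(series)
    return out
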
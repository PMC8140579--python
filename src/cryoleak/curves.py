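"""Constrained damage-curve fitting and critical-temperature extraction.

Two curve families are fit to leakage (or visual damage) vs temperature:

* a four-parameter log-logistic,  v(T) = c + (d - c) / (1 + e^{b (T - u)}),
  where u is the inflection temperature (LT50 under the relative-damage
  convention) and b > 0 the slope for data where damage rises as T falls;
* a Gompertz curve on the adjusted-index (percent) scale,
  I_adj(T) = 100 e^{-b e^{-k T}} with b > 0, k < 0, whose asymmetry decouples
  the temperature of maximum slope (LT_max = ln(b)/k) from LT50.

Constraint modes mirror the standardization lineages: ``anderson_free`` fits
all four logistic parameters (raw R data), ``flint_c0`` pins c = 0 (index of
injury), ``lim_c0_d100`` and ``vd_c0_d100`` pin c = 0 and d = 100 (adjusted
index and quartile visual damage).

Critical temperatures use the relative-damage convention: LT_p is where the
fitted curve crosses p% of its own span c -> d, so LT50 = u exactly for every
logistic mode. An absolute-threshold variant is available behind a flag.

Fits are unweighted least squares on replicate-level points with a
deterministic, derivative-free start; non-convergence is reported via the
``converged`` flag, never papered over.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateDataError, DomainError
from .io import LeakageSeries

CONSTRAINT_MODES = ("anderson_free", "flint_c0", "lim_c0_d100", "vd_c0_d100")

#: Human-readable approach labels used in critical-value tables.
APPROACH_LABELS = {
    "anderson_free": "Anderson",
    "flint_c0": "Flint",
    "lim_c0_d100": "Lim_logistic",
    "vd_c0_d100": "VisualDamage",
    "gompertz": "Lim_gompertz",
}


@dataclass
class LogisticFit:
    """A fitted four-parameter log-logistic damage curve."""

    c: float
    d: float
    b: float
    u: float
    constraint_mode: str
    pseudo_R2: float
    converged: bool
    n_points: int
    sse: float
    species: str | None = None
    genotype: str | None = None

    def __call__(self, T):
        return loglogistic_eval(T, self.c, self.d, self.b, self.u)


@dataclass
class GompertzFit:
    """A fitted Gompertz damage curve on the percent (adjusted-index) scale."""

    b: float
    k: float
    pseudo_R2: float
    converged: bool
    n_points: int
    sse: float
    species: str | None = None
    genotype: str | None = None

    def __call__(self, T):
        return gompertz_eval(T, self.b, self.k)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def loglogistic_eval(T, c, d, b, u):
    """c + (d - c)/(1 + e^{b (T - u)}); total function, overflow-safe."""
    T = np.asarray(T, dtype=float)
    z = np.clip(b * (T - u), -700.0, 700.0)
    out = c + (d - c) / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def gompertz_eval(T, b, k):
    """100 e^{-b e^{-k T}} with b > 0; damage -> 100 as T -> -inf when k < 0."""
    T = np.asarray(T, dtype=float)
    z = np.clip(-k * T, -700.0, 700.0)
    out = 100.0 * np.exp(-b * np.exp(z))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _extract_points(series) -> tuple[np.ndarray, np.ndarray, str | None, str | None]:
    if isinstance(series, LeakageSeries):
        return series.temperatures, series.values, series.species, series.genotype
    t, y = series
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float), None, None


def _check_fittable(t: np.ndarray, y: np.ndarray, n_free: int, flat_tol: float) -> None:
    if len(np.unique(t)) < 4:
        raise DegenerateDataError("need >= 4 distinct temperatures to fit")
    if len(t) < n_free + 1:
        raise DegenerateDataError(
            f"need at least {n_free + 1} points for {n_free} free parameters"
        )
    means = np.array([y[t == tt].mean() for tt in np.unique(t)])
    if np.ptp(means) < flat_tol:
        raise DegenerateDataError("flat response: per-temperature means span < tolerance")


def _mid_cross_temperature(t: np.ndarray, y: np.ndarray) -> float:
    """Temperature where the per-temperature mean response crosses its mid-range.

    Scans from cold to warm (damage decreasing) and linearly interpolates the
    first straddling pair; falls back to the median temperature.
    """
    tu = np.unique(t)
    means = np.array([y[t == tt].mean() for tt in tu])  # tu ascending (cold->warm)
    mid = 0.5 * (means.min() + means.max())
    for i in range(len(tu) - 1):
        y0, y1 = means[i], means[i + 1]
        if (y0 - mid) * (y1 - mid) <= 0 and y0 != y1:
            return float(tu[i] + (mid - y0) * (tu[i + 1] - tu[i]) / (y1 - y0))
    return float(np.median(tu))


def _pseudo_r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_loglogistic(
    series,
    mode: str = "lim_c0_d100",
    *,
    d_max: float = 110.0,
    b_cap: float = 10.0,
    flat_tol: float = 1e-6,
) -> LogisticFit:
    """Fit the log-logistic under the constraint mode's fixed parameters.

    ``series`` is a :class:`LeakageSeries` or a ``(temperatures, values)``
    pair; fitting uses replicate-level points, not temperature means. The
    upper-asymptote bound ``d_max`` gives the free modes soft headroom above
    100 % so the solver does not stick on the boundary for slightly leaky
    data; ``b_cap`` bounds the slope at a transition far sharper than any
    physical damage curve, which keeps step-like (quartile) data from driving
    b to infinity. Degenerate (flat or under-determined) data raise
    :class:`DegenerateDataError`; solver failure returns ``converged=False``.
    """
    if mode not in CONSTRAINT_MODES:
        raise DomainError(f"unknown constraint mode {mode!r}")
    t, y, species, genotype = _extract_points(series)
    fixed_c = 0.0 if mode != "anderson_free" else None
    fixed_d = 100.0 if mode in ("lim_c0_d100", "vd_c0_d100") else None
    n_free = 4 - (fixed_c is not None) - (fixed_d is not None)
    _check_fittable(t, y, n_free, flat_tol)

    tu = np.unique(t)
    means = np.array([y[t == tt].mean() for tt in tu])
    c0 = float(means.min()) if fixed_c is None else 0.0
    d0 = float(np.clip(means.max(), c0 + 1e-6, d_max)) if fixed_d is None else 100.0
    u0 = _mid_cross_temperature(t, y)
    span = float(tu.max() - tu.min())
    b0 = 4.0 / span

    def residuals(theta: np.ndarray) -> np.ndarray:
        i = 0
        if fixed_c is None:
            c = theta[i]
            i += 1
        else:
            c = fixed_c
        if fixed_d is None:
            d = theta[i]
            i += 1
        else:
            d = fixed_d
        b, u = theta[i], theta[i + 1]
        return loglogistic_eval(t, c, d, b, u) - y

    lo, hi, x0 = [], [], []
    if fixed_c is None:
        lo.append(0.0)
        hi.append(np.inf)
        x0.append(max(c0, 0.0))
    if fixed_d is None:
        lo.append(-np.inf)
        hi.append(d_max)
        x0.append(min(d0, d_max))
    lo += [1e-9, -np.inf]
    hi += [b_cap, np.inf]
    x0 += [b0, u0]

    best = None
    any_success = False
    for b_mult in (1.0, 0.25, 4.0):  # deterministic fallback starts
        x_start = list(x0)
        x_start[-2] = b0 * b_mult
        res = least_squares(
            residuals,
            x_start,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        sse = float(np.sum(res.fun**2))
        any_success = any_success or res.success
        if best is None or sse < best[1]:
            best = (res, sse)
    res, sse = best
    theta = list(res.x)
    c = theta.pop(0) if fixed_c is None else fixed_c
    d = theta.pop(0) if fixed_d is None else fixed_d
    b, u = theta
    fit = LogisticFit(
        c=float(c),
        d=float(d),
        b=float(b),
        u=float(u),
        constraint_mode=mode,
        pseudo_R2=_pseudo_r2(y, res.fun),
        converged=bool(any_success and np.isfinite(sse)),
        n_points=len(t),
        sse=sse,
        species=species,
        genotype=genotype,
    )
    if not fit.converged:
        warnings.warn(f"log-logistic fit did not converge (genotype {genotype!r})")
    return fit


def fit_gompertz(series, *, flat_tol: float = 1e-6) -> GompertzFit:
    """Fit the Gompertz curve to adjusted-index (percent) data.

    Parameters are fit as (log b, k) with k bounded negative, which keeps the
    doubly-exponential model well conditioned across the realistic b range
    (1e-4 ... 1e4). Degenerate data raise; non-convergence is flagged.
    """
    t, y, species, genotype = _extract_points(series)
    _check_fittable(t, y, 2, flat_tol)

    tu = np.unique(t)
    span = float(tu.max() - tu.min())
    u0 = _mid_cross_temperature(t, y)
    k0 = -8.0 / span

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_b, k = theta
        z = np.clip(log_b - k * t, -700.0, 700.0)
        return 100.0 * np.exp(-np.exp(z)) - y

    best = None
    any_success = False
    for k_mult in (1.0, 0.5, 2.0, 4.0):
        k_start = max(min(k0 * k_mult, -1e-9), -10.0)
        # place the 50% crossing at u0: log b = ln ln 2 + k * u0
        log_b0 = math.log(math.log(2.0)) + k_start * u0
        res = least_squares(
            residuals,
            [log_b0, k_start],
            bounds=([-np.inf, -10.0], [np.inf, -1e-9]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        sse = float(np.sum(res.fun**2))
        any_success = any_success or res.success
        if best is None or sse < best[1]:
            best = (res, sse)
    res, sse = best
    log_b, k = res.x
    fit = GompertzFit(
        b=float(np.exp(log_b)),
        k=float(k),
        pseudo_R2=_pseudo_r2(y, res.fun),
        converged=bool(any_success and np.isfinite(sse)),
        n_points=len(t),
        sse=sse,
        species=species,
        genotype=genotype,
    )
    if not fit.converged:
        warnings.warn(f"Gompertz fit did not converge (genotype {genotype!r})")
    return fit


def fit_species(
    series_list: Sequence[LeakageSeries],
    mode: str = "lim_c0_d100",
    *,
    gompertz: bool = False,
    **kwargs,
):
    """Fit one curve to the replicate points of all genotypes of a species pooled."""
    series_list = list(series_list)
    if not series_list:
        raise DomainError("empty series pool")
    species = series_list[0].species
    t = np.concatenate([s.temperatures for s in series_list])
    y = np.concatenate([s.values for s in series_list])
    pooled = LeakageSeries(species, f"{species}:pooled", series_list[0].kind, t, y)
    if gompertz:
        return fit_gompertz(pooled, **kwargs)
    return fit_loglogistic(pooled, mode, **kwargs)


# ---------------------------------------------------------------------------
# Critical temperatures
# ---------------------------------------------------------------------------


def lt_from_loglogistic(fit: LogisticFit, p: float, *, absolute: bool = False) -> float:
    """Temperature at which the fitted logistic reaches p% damage.

    Relative convention (default): p% of the fitted span c -> d, so LT50 = u
    exactly. With ``absolute=True``, p is an absolute damage value on the data
    scale; returns NaN (with a warning) when p lies outside the open interval
    (c, d) and is therefore never attained.
    """
    if not 0 < p < 100:
        raise DomainError("p must be in (0, 100)")
    if absolute:
        if not fit.c < p < fit.d:
            warnings.warn(
                f"absolute threshold {p} outside fitted span ({fit.c:.3g}, {fit.d:.3g})"
            )
            return float("nan")
        q = 100.0 * (p - fit.c) / (fit.d - fit.c)
    else:
        q = p
    return fit.u + math.log((100.0 - q) / q) / fit.b


def lt_max_gompertz(fit: GompertzFit) -> float:
    """Temperature of maximum |slope| of the fitted Gompertz: ln(b)/k."""
    if fit.b <= 0:
        raise DomainError("Gompertz b must be > 0")
    return math.log(fit.b) / fit.k


def lt_p_gompertz(fit: GompertzFit, p: float) -> float:
    """Invert the Gompertz: LT_p = (ln b - ln ln(100/p)) / k."""
    if not 0 < p < 100:
        raise DomainError("p must be in (0, 100)")
    if fit.b <= 0:
        raise DomainError("Gompertz b must be > 0")
    return (math.log(fit.b) - math.log(math.log(100.0 / p))) / fit.k


def critical_value_table(
    fits: Mapping[str, LogisticFit | GompertzFit],
    thresholds: Iterable[float] = (20.0, 50.0, 80.0),
    *,
    level: str = "genotype",
    approach: str | None = None,
) -> pd.DataFrame:
    """Build a tidy critical-value table from fitted curves.

    ``fits`` maps genotype (or species) names to fits. Logistic fits yield
    LT_p rows for each threshold; Gompertz fits additionally yield an LTmax
    row. Non-converged fits are omitted with a warning so downstream tables
    show the genotype as missing rather than carrying garbage.
    """
    rows = []
    for name, fit in fits.items():
        if not fit.converged:
            warnings.warn(f"{name!r}: fit not converged; omitted from table")
            continue
        if isinstance(fit, GompertzFit):
            label = approach or APPROACH_LABELS["gompertz"]
            for p in thresholds:
                rows.append((level, name, label, f"LT{p:g}", lt_p_gompertz(fit, p)))
            rows.append((level, name, label, "LTmax", lt_max_gompertz(fit)))
        else:
            label = approach or APPROACH_LABELS[fit.constraint_mode]
            for p in thresholds:
                rows.append((level, name, label, f"LT{p:g}", lt_from_loglogistic(fit, p)))
    return pd.DataFrame(
        rows, columns=["level", "name", "approach", "metric", "temperature_C"]
    )
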
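"""Liquid-nitrogen vs autoclave control calibration.

Autoclaving damages woody tissue more than liquid-nitrogen immersion, so the
two positive controls sit on different conductivity scales. A zero-intercept
Deming ("least rectangle") regression — errors in both axes, both read by the
same instrument — calibrates one against the other:

    Conductivity_LN = slope x Conductivity_autoclave        (slope ~ 0.576)

With the error-variance ratio delta, the through-origin Deming slope minimises
sum (y - s x)^2 / (delta + s^2); setting the derivative to zero gives the
closed-form positive root of

    Sxy s^2 - (Syy - delta Sxx) s - delta Sxy = 0.

For delta = 1 this is orthogonal regression through the origin and satisfies
reciprocity: slope(y~x) * slope(x~y) = 1.

Datasets standardized against an autoclave control are re-expressed under an
assumed liquid-nitrogen control by dividing relative leakage by the slope
(capped at 1: relative leakage above 100 % is physically meaningless). The
adjusted index I_adj is algebraically invariant under this conversion — the
scale factor cancels between numerator and denominator — which is why it is
the index of choice for cross-study comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateDataError, DomainError
from .io import ConductivityRecord, LeakageSeries
from .standardize import BaselineSpec, MaximumSpec, standardize_dataset
from .curves import LogisticFit, fit_loglogistic


@dataclass
class DemingFit:
    """Zero-intercept Deming regression result."""

    slope: float
    ci_low: float
    ci_high: float
    r2_xy: float  # residuals taken in y, SS_tot about y-bar
    r2_yx: float  # residuals taken in x, SS_tot about x-bar
    delta: float
    n_used: int
    outlier_idx: list[int] = field(default_factory=list)
    n_boot: int = 0
    seed: int | None = None


@dataclass
class RatioStats:
    """Mean and dispersion of per-tube conductivity ratios."""

    mean: float
    sd: float
    n: int
    keys: list


def deming_slope(x: np.ndarray, y: np.ndarray, delta: float = 1.0) -> float:
    """Closed-form through-origin Deming slope (positive root)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    sxy = float(np.sum(x * y))
    if sxx <= 0:
        raise DegenerateDataError("all-zero x values")
    if sxy == 0:
        raise DegenerateDataError("x and y are orthogonal; slope undefined")
    a = syy - delta * sxx
    return (a + np.sqrt(a * a + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)


def _bootstrap_slopes(
    x: np.ndarray, y: np.ndarray, delta: float, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    sxx = np.sum(xb * xb, axis=1)
    syy = np.sum(yb * yb, axis=1)
    sxy = np.sum(xb * yb, axis=1)
    a = syy - delta * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = (a + np.sqrt(a * a + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)
    return slopes[np.isfinite(slopes)]


def deming_zero_intercept(
    x: Sequence[float],
    y: Sequence[float],
    delta: float = 1.0,
    *,
    outlier_policy: str = "mad3",
    n_boot: int = 10_000,
    seed: int = 0,
) -> DemingFit:
    """Fit y = slope * x with errors in both axes.

    ``x`` and ``y`` are paired positive conductivities (autoclave, liquid
    nitrogen). Outlier handling (``outlier_policy="mad3"``): perpendicular
    residuals from an initial all-data fit are flagged when exceeding
    3 x 1.4826 x MAD, removed once, and the slope recomputed; ``"none"``
    disables this. The 95 % CI is a seeded nonparametric bootstrap over pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("x and y must be paired")
    if len(x) < 3:
        raise DomainError("need at least 3 pairs")
    if delta <= 0:
        raise DomainError("delta must be > 0")

    outliers: list[int] = []
    if outlier_policy == "mad3":
        s0 = deming_slope(x, y, delta)
        r = (y - s0 * x) / np.sqrt(1.0 + s0 * s0)
        mad = float(np.median(np.abs(r - np.median(r))))
        if mad > 0:
            flagged = np.abs(r - np.median(r)) > 3.0 * 1.4826 * mad
            outliers = [int(i) for i in np.flatnonzero(flagged)]
    elif outlier_policy != "none":
        raise DomainError(f"unknown outlier policy {outlier_policy!r}")

    keep = np.setdiff1d(np.arange(len(x)), outliers)
    if len(keep) < 3:
        raise DomainError("fewer than 3 pairs remain after outlier removal")
    xk, yk = x[keep], y[keep]
    slope = deming_slope(xk, yk, delta)

    rng = np.random.default_rng(seed)
    boots = _bootstrap_slopes(xk, yk, delta, n_boot, rng) if n_boot > 0 else np.array([])
    if len(boots):
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low = ci_high = slope

    ss_y = float(np.sum((yk - yk.mean()) ** 2))
    ss_x = float(np.sum((xk - xk.mean()) ** 2))
    r2_xy = 1.0 - float(np.sum((yk - slope * xk) ** 2)) / ss_y if ss_y > 0 else float("nan")
    r2_yx = 1.0 - float(np.sum((xk - yk / slope) ** 2)) / ss_x if ss_x > 0 else float("nan")

    return DemingFit(
        slope=float(slope),
        ci_low=float(min(ci_low, slope)),
        ci_high=float(max(ci_high, slope)),
        r2_xy=r2_xy,
        r2_yx=r2_yx,
        delta=delta,
        n_used=len(keep),
        outlier_idx=outliers,
        n_boot=n_boot,
        seed=seed,
    )


def convert_to_ln_standard(R_auto, slope: float, cap: float | None = 1.0):
    """Re-express autoclave-relative leakage under a liquid-nitrogen standard.

    R_ln = R_auto / slope, capped at ``cap`` (default 1.0) because relative
    leakage above 100 % of the control is physically meaningless; pass
    ``cap=None`` for the raw algebraic conversion. Capped points trigger a
    warning with their count.
    """
    if slope <= 0:
        raise DomainError("slope must be > 0")
    R_auto = np.asarray(R_auto, dtype=float)
    out = R_auto / slope
    if cap is not None:
        n_capped = int(np.sum(out > cap))
        if n_capped:
            warnings.warn(f"{n_capped} converted value(s) capped at {cap}")
        out = np.minimum(out, cap)
    return float(out) if out.ndim == 0 else out


def mean_control_ratio(
    numerator: Mapping, denominator: Mapping
) -> RatioStats:
    """Mean of per-tube ratios numerator[k]/denominator[k] over shared keys.

    Both arguments map a tube-pairing key to a conductivity. Keys present in
    only one mapping are orphans and abort with an error listing them.
    """
    orphans = set(numerator) ^ set(denominator)
    if orphans:
        raise DomainError(f"unpaired tubes: {sorted(orphans, key=str)}")
    if not numerator:
        raise DomainError("no pairs supplied")
    keys = sorted(numerator, key=str)
    ratios = np.array([numerator[k] / denominator[k] for k in keys], dtype=float)
    return RatioStats(
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        n=len(ratios),
        keys=keys,
    )


@dataclass
class ConvertedRefit:
    """Fits of R and I series before and after liquid-nitrogen conversion."""

    fits_autoclave: dict[str, dict[str, LogisticFit]]  # kind -> genotype -> fit
    fits_ln: dict[str, dict[str, LogisticFit]]
    iadj_series: list[LeakageSeries]  # control-method invariant


def refit_under_converted_control(
    records: Iterable[ConductivityRecord],
    slope: float,
    *,
    modes: Mapping[str, str] = {"R": "anderson_free", "I": "flint_c0"},
    cap: float | None = 1.0,
    baseline: BaselineSpec | None = None,
    maximum: MaximumSpec | None = None,
) -> ConvertedRefit:
    """Recompute and refit R and I under an assumed liquid-nitrogen control.

    The conversion divides each tube's relative leakage by ``slope`` (capped),
    implemented as L_T' = min(L_T/slope, cap * L_K) so downstream
    standardization is reused unchanged. I_adj is returned from the original
    records only: the control scale cancels from its formula, so conversion
    cannot change it (asserted in the test suite).
    """
    if slope <= 0:
        raise DomainError("slope must be > 0")
    records = list(records)
    converted = []
    for r in records:
        if r.L_K is None:
            converted.append(r)
            continue
        lt = r.L_T / slope
        if cap is not None:
            lt = min(lt, cap * r.L_K)
        converted.append(
            ConductivityRecord(
                species=r.species,
                genotype=r.genotype,
                replicate=r.replicate,
                temperature_C=r.temperature_C,
                L_T=lt,
                L_K=r.L_K,
                control_type="liquid_nitrogen",
                incubation_days=r.incubation_days,
            )
        )

    def _fit_all(recs, kind, mode):
        series = standardize_dataset(recs, kind, baseline, maximum)
        return {
            s.genotype: fit_loglogistic(s, mode) for s in series if s.fit_eligible()
        }

    fits_auto = {kind: _fit_all(records, kind, mode) for kind, mode in modes.items()}
    fits_ln = {kind: _fit_all(converted, kind, mode) for kind, mode in modes.items()}
    iadj = standardize_dataset(records, "I_adj", baseline, maximum)
    return ConvertedRefit(fits_autoclave=fits_auto, fits_ln=fits_ln, iadj_series=iadj)
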
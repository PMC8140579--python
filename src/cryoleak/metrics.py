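"""Cross-method validation: correlations, bias/RMSE grids, LST.

Conventions: bias = mean(pred - obs), with the electrolyte-leakage quantity
as ``pred`` and the reference (visual damage, other approach) as ``obs``
throughout, so a positive bias means leakage estimates are warmer / larger.
Fitted-curve comparisons are made on fitted values over a 1 °C temperature
grid, not raw points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .curves import GompertzFit, LogisticFit, lt_from_loglogistic, lt_p_gompertz
from .io import VisualDamageRecord

#: Fig-style contour cutoffs for the threshold grid masks.
GRID_CUTOFFS = {"correlation": 0.55, "bias_abs_C": 5.0, "rmse_C": 7.0}


def bias(pred, obs) -> float:
    """mean(pred - obs); sign convention: first argument minus reference."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise DomainError("pred and obs must be paired")
    return float(np.mean(pred - obs))


def rmse(pred, obs) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise DomainError("pred and obs must be paired")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


# ---------------------------------------------------------------------------
# Critical-value correlation matrix
# ---------------------------------------------------------------------------


def critical_value_correlations(
    wide: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations between critical-value columns.

    ``wide`` is indexed by genotype (or species) with one column per
    approach/metric combination (e.g. ``"Lim_logistic:LT50"``). Returns
    ``(rho, p)`` symmetric DataFrames; cells with fewer than 3 aligned pairs
    are NaN. ``method`` is "pearson" or "spearman". Metrics observed at
    different levels (e.g. LTE at species level) should be correlated in a
    separate call at that level.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    cols = list(wide.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                continue
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = corr_fn(pair[a].to_numpy(), pair[b].to_numpy())
            rho.loc[a, b] = rho.loc[b, a] = float(r)
            pval.loc[a, b] = pval.loc[b, a] = float(p)
    return rho, pval


# ---------------------------------------------------------------------------
# Threshold grid (EL vs VD across damage levels)
# ---------------------------------------------------------------------------


def _lt(fit, p: float) -> float:
    if isinstance(fit, GompertzFit):
        return lt_p_gompertz(fit, p)
    return lt_from_loglogistic(fit, p)


@dataclass
class ThresholdGrid:
    """Across-genotype agreement between EL and VD critical values.

    Cell (i, j) compares LT at ``el_thresholds[i]`` % leakage against LT at
    ``vd_thresholds[j]`` % visual damage across the shared genotypes: Pearson
    correlation, bias (°C, EL - VD), RMSE (°C) and n.
    """

    el_thresholds: np.ndarray
    vd_thresholds: np.ndarray
    correlation: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    n: np.ndarray

    def masks(self, cutoffs: Mapping[str, float] = GRID_CUTOFFS) -> dict[str, np.ndarray]:
        """Boolean acceptance layers at the standard contour cutoffs."""
        return {
            "correlation": self.correlation > cutoffs["correlation"],
            "bias": np.abs(self.bias) < cutoffs["bias_abs_C"],
            "rmse": self.rmse < cutoffs["rmse_C"],
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.el_thresholds):
            for j, q in enumerate(self.vd_thresholds):
                rows.append(
                    {
                        "el_pct": p,
                        "vd_pct": q,
                        "correlation": self.correlation[i, j],
                        "bias_C": self.bias[i, j],
                        "rmse_C": self.rmse[i, j],
                        "n": self.n[i, j],
                    }
                )
        return pd.DataFrame(rows)


def threshold_grid(
    el_fits: Mapping[str, LogisticFit | GompertzFit],
    vd_fits: Mapping[str, LogisticFit | GompertzFit],
    thresholds: Sequence[float] = tuple(range(10, 100, 10)),
) -> ThresholdGrid:
    """Build the LT10..LT90 x LT10..LT90 agreement grid across genotypes."""
    shared = sorted(set(el_fits) & set(vd_fits))
    if not shared:
        raise DomainError("no genotypes shared between EL and VD fits")
    thr = np.asarray(thresholds, dtype=float)
    k = len(thr)
    corr = np.full((k, k), np.nan)
    bias_g = np.full((k, k), np.nan)
    rmse_g = np.full((k, k), np.nan)
    n_g = np.zeros((k, k), dtype=int)
    el_lt = np.array([[_lt(el_fits[g], p) for g in shared] for p in thr])
    vd_lt = np.array([[_lt(vd_fits[g], q) for g in shared] for q in thr])
    for i in range(k):
        for j in range(k):
            a, b = el_lt[i], vd_lt[j]
            ok = np.isfinite(a) & np.isfinite(b)
            n_g[i, j] = int(ok.sum())
            if n_g[i, j] == 0:
                continue
            bias_g[i, j] = bias(a[ok], b[ok])
            rmse_g[i, j] = rmse(a[ok], b[ok])
            if n_g[i, j] >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
                corr[i, j] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return ThresholdGrid(thr, thr.copy(), corr, bias_g, rmse_g, n_g)


# ---------------------------------------------------------------------------
# Fitted-value approach comparison (Fig. 6-style)
# ---------------------------------------------------------------------------


@dataclass
class ApproachComparison:
    """Paired fitted values of two approaches on a shared temperature grid."""

    t_grid: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    bias: float
    rmse: float
    band_fraction: float  # fraction of grid points within `band` of the 1:1 line
    band: float
    restricted_bias: float
    restricted_rmse: float
    restrict: tuple[float, float] | None


def compare_fitted_approaches(
    fit_a,
    fit_b,
    t_grid: Sequence[float],
    *,
    scale_a: float = 1.0,
    scale_b: float = 1.0,
    restrict: tuple[float, float] | None = None,
    band: float = 15.0,
) -> ApproachComparison:
    """Compare two fitted damage curves on a temperature grid.

    Values are ``scale_*`` x fitted curve (use ``scale_a=100`` to put an
    R-scale Anderson fit on the percent scale of a Lim fit). ``restrict``
    bounds, when given, limit the restricted statistics to grid points whose
    *second* (reference, e.g. Lim) value lies inside them. ``band`` is the
    half-width (percentage points) of the 1:1 agreement band.
    """
    t = np.asarray(t_grid, dtype=float)
    a = scale_a * np.asarray(fit_a(t), dtype=float)
    b = scale_b * np.asarray(fit_b(t), dtype=float)
    restricted_bias = restricted_rmse = float("nan")
    if restrict is not None:
        lo, hi = restrict
        mask = (b >= lo) & (b <= hi)
        if mask.any():
            restricted_bias = bias(a[mask], b[mask])
            restricted_rmse = rmse(a[mask], b[mask])
        else:
            warnings.warn(
                f"no grid points with reference value in [{lo}, {hi}]; "
                "restricted statistics undefined"
            )
    return ApproachComparison(
        t_grid=t,
        values_a=a,
        values_b=b,
        bias=bias(a, b),
        rmse=rmse(a, b),
        band_fraction=float(np.mean(np.abs(a - b) <= band)),
        band=band,
        restricted_bias=restricted_bias,
        restricted_rmse=restricted_rmse,
        restrict=restrict,
    )


# ---------------------------------------------------------------------------
# Lowest survival temperature
# ---------------------------------------------------------------------------


def lowest_survival_temperature(
    records: Iterable[VisualDamageRecord], threshold: float = 50.0
) -> float | None:
    """Coldest tested temperature at which no segment exceeds ``threshold`` % damage.

    Temperatures are judged independently (no monotonicity repair). If the
    warmest *freezing* temperature already has a segment above threshold the
    LST is undefined and None is returned with a warning.
    """
    records = list(records)
    if not records:
        raise DomainError("no visual damage records supplied")
    by_temp: dict[float, list[float]] = {}
    for r in records:
        by_temp.setdefault(r.temperature_C, []).append(r.damage_pct)
    temps = sorted(by_temp, reverse=True)  # warm -> cold
    freezing = [t for t in temps if t < 0]
    if len(by_temp) < 2:
        raise DomainError("need records at >= 2 temperatures")
    if freezing and max(by_temp[freezing[0]]) > threshold:
        warnings.warn(
            f"damage exceeds {threshold}% at the warmest freezing temperature "
            f"({freezing[0]} °C); LST undefined"
        )
        return None
    ok = [t for t in temps if max(by_temp[t]) <= threshold]
    if not ok:
        warnings.warn("no temperature with all segments at or below threshold")
        return None
    return float(min(ok))
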
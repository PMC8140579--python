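"""Synthetic freeze-thaw datasets with known ground truth.

The generator emulates a multi-species electrolyte-leakage campaign:
``n_species`` species x ``n_genotypes`` genotypes x ``n_replicates`` tubes per
treatment over the standard seven-temperature design {4, -10, -20, -30, -40,
-60, -80 °C}. Each genotype carries a latent logistic damage curve

    D(T) = 1 / (1 + e^{b* (T - u*)})        in [0, 1],

and a tube frozen at T reads

    L_T = P (f0 + (m - f0) D(T)) (1 + eps),      eps ~ N(0, sd)
    L_K = P (1 + eps)                  autoclave control
    L_K = P m (1 + eps)                liquid-nitrogen control

where P is the tube's total electrolyte pool (µS/cm), f0 the handling-leakage
fraction (baseline at 4 °C), and m the maximum freezing-induced leakage as a
fraction of autoclave leakage (default 0.58 — woody maple twigs leak just
over half their heat-extractable electrolytes even in liquid nitrogen). The
relative leakage R therefore plateaus at m below ~ -40 °C and the adjusted
index I_adj plateaus at 100.

Noise is multiplicative Gaussian: conductivity errors scale with magnitude,
matching the larger scatter seen on big, leaky samples. Visual damage comes
from a distinct curve — shifted ``vd_offset`` °C colder and steeper by
``vd_slope_mult`` — then snapped to the quartile scoring scale, so EL-vs-VD
agreement analyses have genuinely different curves to compare.

All randomness flows from ``SimConfig.seed`` through per-purpose child
streams, so leakage, visual-damage, control-pair and DTA draws share one
genotype truth table and are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .io import ConductivityRecord, DTATrace, VisualDamageRecord

STANDARD_TEMPERATURES = (4.0, -10.0, -20.0, -30.0, -40.0, -60.0, -80.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic campaign (defaults = study design)."""

    n_species: int = 12
    n_genotypes: int = 3
    n_replicates: int = 3
    temperatures: tuple[float, ...] = STANDARD_TEMPERATURES
    pool_conductivity: float = 150.0  # µS/cm, autoclave-extractable pool
    f0: float = 0.10  # handling-leakage fraction at 4 °C
    m: float = 0.58  # max freezing-induced leakage / autoclave leakage
    noise_sd: float = 0.03  # fractional (multiplicative) noise
    u_range: tuple[float, float] = (-28.0, -12.0)  # species LT50 range, °C
    u_jitter: float = 1.5  # genotype-level spread around the species mean, °C
    b_range: tuple[float, float] = (0.15, 0.40)  # logistic slope range, 1/°C
    vd_offset: float = -3.0  # visual-damage curve shift, °C
    vd_slope_mult: float = 1.5  # visual damage accrues faster than leakage
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 <= self.f0 < self.m <= 1:
            raise DomainError("need 0 <= f0 < m <= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if min(self.n_species, self.n_genotypes, self.n_replicates) < 1:
            raise DomainError("counts must be positive")


def damage_curve(T, u: float, b: float):
    """Latent damage fraction D(T) = 1/(1 + e^{b (T - u)})."""
    T = np.asarray(T, dtype=float)
    out = 1.0 / (1.0 + np.exp(np.clip(b * (T - u), -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def truth_table(config: SimConfig) -> pd.DataFrame:
    """Per-genotype latent parameters (u*, b*, m, f0), deterministic in the seed."""
    rng = _rng(config, 0)
    rows = []
    for si in range(config.n_species):
        species = f"sp{si + 1:02d}"
        u_species = rng.uniform(*config.u_range)
        for gi in range(config.n_genotypes):
            rows.append(
                {
                    "species": species,
                    "genotype": f"{species}-g{gi + 1}",
                    "u_star": u_species + rng.uniform(-config.u_jitter, config.u_jitter),
                    "b_star": rng.uniform(*config.b_range),
                    "m": config.m,
                    "f0": config.f0,
                }
            )
    return pd.DataFrame(rows)


def simulate_leakage_experiment(
    config: SimConfig, control_type: str = "autoclave_120"
) -> tuple[list[ConductivityRecord], pd.DataFrame]:
    """Generate conductivity records plus the truth table they were drawn from.

    ``control_type`` selects the post-control read: "autoclave_120" gives
    L_K = P(1+eps); "liquid_nitrogen" gives L_K = P m (1+eps).
    """
    if control_type not in ("autoclave_120", "liquid_nitrogen"):
        raise DomainError(f"unsupported control_type {control_type!r}")
    truth = truth_table(config)
    rng = _rng(config, 1)
    k_scale = config.m if control_type == "liquid_nitrogen" else 1.0
    records: list[ConductivityRecord] = []
    for row in truth.itertuples():
        for rep in range(1, config.n_replicates + 1):
            for T in config.temperatures:
                D = damage_curve(T, row.u_star, row.b_star)
                frac = config.f0 + (config.m - config.f0) * D
                lt = config.pool_conductivity * frac * (
                    1.0 + rng.normal(0.0, config.noise_sd)
                )
                lk = config.pool_conductivity * k_scale * (
                    1.0 + rng.normal(0.0, config.noise_sd)
                )
                records.append(
                    ConductivityRecord(
                        species=row.species,
                        genotype=row.genotype,
                        replicate=rep,
                        temperature_C=T,
                        L_T=max(lt, 0.0),
                        L_K=max(lk, 1e-9),
                        control_type=control_type,
                    )
                )
    return records, truth


def round_to_quartile(value: float) -> float:
    """Snap a continuous damage percentage to {0, 25, 50, 75, 100}, ties toward 50."""
    levels = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
    dist = np.abs(levels - value)
    best = dist.min()
    candidates = levels[np.isclose(dist, best)]
    return float(min(candidates, key=lambda c: abs(c - 50.0)))


def simulate_visual_damage(config: SimConfig) -> list[VisualDamageRecord]:
    """Quartile-scale browning scores from the shifted, steeper VD curve.

    Shares the genotype truth table with :func:`simulate_leakage_experiment`
    so EL-vs-VD validation runs on matched ground truth.
    """
    truth = truth_table(config)
    rng = _rng(config, 2)
    records: list[VisualDamageRecord] = []
    for row in truth.itertuples():
        u_vd = row.u_star + config.vd_offset
        b_vd = row.b_star * config.vd_slope_mult
        for rep in range(1, config.n_replicates + 1):
            for T in config.temperatures:
                cont = 100.0 * damage_curve(T, u_vd, b_vd)
                cont *= 1.0 + rng.normal(0.0, config.noise_sd)
                cont = float(np.clip(cont, 0.0, 100.0))
                records.append(
                    VisualDamageRecord(
                        species=row.species,
                        genotype=row.genotype,
                        replicate=rep,
                        temperature_C=T,
                        damage_pct=round_to_quartile(cont),
                    )
                )
    return records


def simulate_control_pairs(
    config: SimConfig,
    slope: float = 0.576,
    n_pairs: int = 176,
    size_range: tuple[float, float] = (0.5, 1.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (autoclave, liquid-nitrogen) conductivities y = slope * x.

    Tube-to-tube spread comes from a uniform size factor (stem diameter
    varies), and both axes carry independent multiplicative noise — the
    errors-in-both-axes structure Deming regression assumes.
    """
    if n_pairs < 1:
        raise DomainError("n_pairs must be positive")
    rng = _rng(config, 3)
    base = config.pool_conductivity * rng.uniform(*size_range, size=n_pairs)
    x = base * (1.0 + rng.normal(0.0, config.noise_sd, size=n_pairs))
    y = slope * base * (1.0 + rng.normal(0.0, config.noise_sd, size=n_pairs))
    return x, y


def simulate_dta_trace(
    config: SimConfig,
    exotherm_temps: Sequence[float] = (-36.0,),
    amplitudes_mV: Sequence[float] | None = None,
    *,
    genotype: str = "g1",
    trace_id: int = 0,
    start_C: float = 4.0,
    end_C: float = -60.0,
    rate_C_per_h: float = -4.0,
    dt_s: float = 10.0,
    width_C: float = 0.3,
    noise_sd_mV: float = 0.02,
    drift_mV: float = 0.05,
) -> DTATrace:
    """A cooling-ramp voltage trace with Gaussian exotherm bumps.

    The ramp follows the standard protocol (-4 °C/hour from +4 to -60 °C).
    Bump amplitudes default to 8 x the noise sd; ``width_C`` is the Gaussian
    sd of the heat-release pulse in temperature units (real exotherms release
    their heat over well under a degree of the ramp). A small linear drift
    exercises the baseline subtraction. ``trace_id`` seeds an independent
    noise stream per trace.
    """
    if rate_C_per_h >= 0:
        raise DomainError("cooling rate must be negative")
    rng = np.random.default_rng([config.seed, 4, trace_id])
    duration_s = (end_C - start_C) / rate_C_per_h * 3600.0
    t = np.arange(0.0, duration_s + dt_s, dt_s)
    T = start_C + rate_C_per_h * t / 3600.0
    if amplitudes_mV is None:
        amplitudes_mV = [8.0 * noise_sd_mV] * len(exotherm_temps)
    v = drift_mV * t / t[-1]
    for T0, A in zip(exotherm_temps, amplitudes_mV):
        v = v + A * np.exp(-((T - T0) ** 2) / (2.0 * width_C**2))
    if noise_sd_mV > 0:
        v = v + rng.normal(0.0, noise_sd_mV, size=len(t))
    return DTATrace(genotype=genotype, time_s=t, temperature_C=T, voltage_mV=v)


def records_to_frame(records) -> pd.DataFrame:
    """Serialize conductivity or visual-damage records to their CSV schema."""
    rows = []
    for r in records:
        if isinstance(r, ConductivityRecord):
            rows.append(
                {
                    "species": r.species,
                    "genotype": r.genotype,
                    "replicate": r.replicate,
                    "temperature_C": r.temperature_C,
                    "L_T_uS": r.L_T,
                    "L_K_uS": r.L_K if r.L_K is not None else "",
                    "control_type": r.control_type,
                    "incubation_days": (
                        r.incubation_days if r.incubation_days is not None else ""
                    ),
                }
            )
        elif isinstance(r, VisualDamageRecord):
            rows.append(
                {
                    "species": r.species,
                    "genotype": r.genotype,
                    "replicate": r.replicate,
                    "temperature_C": r.temperature_C,
                    "damage_pct": r.damage_pct,
                }
            )
        else:
            raise DomainError(f"cannot serialize {type(r).__name__}")
    return pd.DataFrame(rows)
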
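"""Exotherm detection in differential-thermal-analysis voltage traces.

When plant tissue is cooled, extracellular water freezes first at mild
sub-zero temperatures — a benign high-temperature exotherm (HTE). Supercooled
intracellular water freezes much colder (down to the ~ -42 °C homogeneous
nucleation limit); that low-temperature exotherm (LTE) marks lethal
intracellular ice and is the DTA estimate of cold hardiness.

Detection pipeline: moving-average smoothing (half-°C window) to tame
sample-to-sample noise, a running-median baseline over a several-°C window
(robust to the ~1 °C-wide exotherm bumps), then peak calling on the
baseline-subtracted smoothed signal with a prominence floor of k x the robust
raw-noise scale (1.4826 x MAD of the raw residual — an exotherm must stand
out against the instrument noise amplitude, not merely against the smoothed
trace). Peaks are classed HTE or LTE by a temperature cutoff.
The whole pipeline operates in the sample domain, so it is invariant to
additive voltage offsets (median subtraction) and to uniform time rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_widths

from .errors import DomainError
from .io import DTATrace

#: HTEs occur at relatively warm sub-zero temperatures; this default separates
#: them from deep-supercooling LTEs and is configurable per call.
DEFAULT_HTE_CUTOFF_C = -15.0


@dataclass(frozen=True)
class ExothermPeak:
    temperature_C: float
    prominence_mV: float
    width_C: float
    klass: str  # "HTE" | "LTE"


def _odd(n: int) -> int:
    return max(3, n | 1)


def detect_exotherms(
    trace: DTATrace,
    *,
    baseline_window_C: float = 5.0,
    smooth_C: float = 0.5,
    prominence_k: float = 6.0,
    hte_cutoff_C: float = DEFAULT_HTE_CUTOFF_C,
    min_span_C: float = 10.0,
) -> list[ExothermPeak]:
    """Detect exotherm peaks in a cooling trace.

    Returns all peaks (HTE and LTE) ordered warm -> cold; callers that follow
    the standard protocol discard the HTEs (see :func:`lte_peaks`). Raises if
    the cooling span is below ``min_span_C`` or the trace is shorter than the
    baseline window.
    """
    T = trace.temperature_C
    v = trace.voltage_mV
    n = len(v)
    span = trace.span_C
    if span < min_span_C:
        raise DomainError(f"cooling span {span:.1f} °C < required {min_span_C} °C")
    samples_per_C = (n - 1) / span
    w_base = _odd(int(round(baseline_window_C * samples_per_C)))
    if w_base >= n:
        raise DomainError("trace shorter than the baseline window")
    w_smooth = _odd(int(round(smooth_C * samples_per_C)))

    smoothed = uniform_filter1d(v, size=w_smooth, mode="nearest")
    baseline = (
        pd.Series(smoothed).rolling(w_base, center=True, min_periods=1).median().to_numpy()
    )
    signal = smoothed - baseline
    # Noise scale comes from the RAW residual: the prominence floor must clear
    # raw-noise amplitude, not the (much smaller) smoothed-noise amplitude.
    raw_resid = v - baseline
    mad = float(np.median(np.abs(raw_resid - np.median(raw_resid))))
    noise_sd = 1.4826 * mad
    floor = max(prominence_k * noise_sd, 1e-12)

    idx, props = find_peaks(signal, prominence=floor)
    peaks: list[ExothermPeak] = []
    if len(idx):
        widths_samples = peak_widths(signal, idx, rel_height=0.5)[0]
        for i, peak_i in enumerate(idx):
            t_peak = float(T[peak_i])
            peaks.append(
                ExothermPeak(
                    temperature_C=t_peak,
                    prominence_mV=float(props["prominences"][i]),
                    width_C=float(widths_samples[i] / samples_per_C),
                    klass="HTE" if t_peak > hte_cutoff_C else "LTE",
                )
            )
    peaks.sort(key=lambda p: -p.temperature_C)
    return peaks


def lte_peaks(peaks: Sequence[ExothermPeak]) -> list[ExothermPeak]:
    return [p for p in peaks if p.klass == "LTE"]


def species_lte_summary(
    peaks_by_genotype: Mapping[str, Sequence[ExothermPeak]]
) -> float | None:
    """Species-mean LTE temperature over genotypes.

    Each genotype contributes the temperature of its most prominent LTE
    (pooled stem segments in one cell can produce several true LTEs; all stay
    in the record, the summary uses the strongest). Genotypes without a
    detected LTE are excluded with a warning; None if no genotype has one.
    """
    per_genotype = []
    for genotype, peaks in peaks_by_genotype.items():
        ltes = lte_peaks(peaks)
        if not ltes:
            warnings.warn(f"genotype {genotype!r}: no LTE detected; excluded")
            continue
        strongest = max(ltes, key=lambda p: p.prominence_mV)
        per_genotype.append(strongest.temperature_C)
    if not per_genotype:
        warnings.warn("no genotype contributed an LTE; species mean undefined")
        return None
    return float(np.mean(per_genotype))


def peaks_to_frame(peaks: Sequence[ExothermPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "temperature_C": p.temperature_C,
                "prominence_mV": p.prominence_mV,
                "width_C": p.width_C,
                "klass": p.klass,
            }
            for p in peaks
        ],
        columns=["temperature_C", "prominence_mV", "width_C", "klass"],
    )
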
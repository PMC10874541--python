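"""DNA-content cell-cycle gating and phase-stratified peroxisome profiles.

Integrated DNA-stain intensity indexes DNA content: the G1 population sits
at 2N, G2/M at 4N (twice 2N), and S bridges the two.  Gates are located
from the kernel-smoothed log-intensity density and applied as simple
boundaries on integrated DNA signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spots import CellRecord

PHASES = ("G1", "S", "G2M")

#: fallback gate multipliers (fractions of the 2N peak) when no 4N mode is found
FALLBACK_G1_UPPER = 1.3
FALLBACK_S_UPPER = 1.7


class DegenerateDistributionWarning(UserWarning):
    """Raised when the DNA histogram lacks a usable 4N mode."""


@dataclass(frozen=True)
class PhaseGates:
    """DNA-content boundaries separating G1 / S / G2-M."""

    peak_2n: float
    peak_4n: float
    g1_upper: float
    s_upper: float
    method: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.peak_2n < self.g1_upper < self.s_upper):
            raise ValueError("gates must satisfy peak_2n < g1_upper < s_upper")


def _kde_log_density(values: np.ndarray, grid_size: int = 512):
    logv = np.log(values)
    kde = stats.gaussian_kde(logv, bw_method="silverman")
    bandwidth = float(kde.factor * logv.std(ddof=1))
    lo, hi = logv.min(), logv.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    return grid, kde(grid), bandwidth


def _local_modes(grid: np.ndarray, dens: np.ndarray) -> np.ndarray:
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    return np.where(interior)[0] + 1


def fit_dna_gates(
    integrated_dna_values: Sequence[float],
    min_cells: int = 200,
    search_window: tuple[float, float] = (1.7, 2.3),
    cv_multiplier: float = 1.6,
) -> PhaseGates:
    """Locate the 2N and 4N modes and derive phase boundaries.

    The 2N peak is the global mode of a kernel-smoothed density of
    log intensities (Silverman bandwidth); the 4N peak is the strongest
    local mode within ``search_window`` times the 2N peak.  The G1 upper
    bound is ``peak_2n * (1 + m*cv)`` and the S upper bound
    ``peak_4n * (1 - m*cv)`` with ``m = cv_multiplier`` and the CV
    estimated from the half-width of the 2N peak; m = 1.6 balances
    peak-tail leakage against truncation of the S-phase bridge.  If no 4N
    mode exists, fixed multipliers (1.3x, 1.7x) of the 2N peak are used
    and a degenerate-distribution warning issued.
    """
    values = np.asarray(integrated_dna_values, dtype=float)
    if len(values) < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {len(values)}")
    if np.any(values <= 0):
        raise ValueError("integrated DNA values must be positive")

    if np.ptp(values) < 1e-12 * values.mean():
        peak_2n = float(values[0])
        warnings.warn(
            "all DNA values identical; falling back to fixed gate multipliers",
            DegenerateDistributionWarning,
        )
        return PhaseGates(
            peak_2n=peak_2n,
            peak_4n=2.0 * peak_2n,
            g1_upper=FALLBACK_G1_UPPER * peak_2n,
            s_upper=FALLBACK_S_UPPER * peak_2n,
            method={"mode": "fallback", "reason": "degenerate"},
        )

    grid, dens, bandwidth = _kde_log_density(values)
    modes = _local_modes(grid, dens)
    i2n = modes[np.argmax(dens[modes])] if len(modes) else int(np.argmax(dens))
    peak_2n = float(np.exp(grid[i2n]))

    # CV from the half-width of the 2N peak: on the log scale a lognormal
    # peak is Gaussian with sd ~ cv, and FWHM = 2*sqrt(2 ln 2) * sd.  The
    # KDE convolves the peak with its bandwidth, so deconvolve it back out.
    half = dens[i2n] / 2.0
    left = i2n
    while left > 0 and dens[left] > half:
        left -= 1
    right = i2n
    while right < len(dens) - 1 and dens[right] > half:
        right += 1
    fwhm = grid[right] - grid[left]
    smoothed_sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    cv_hat = float(np.sqrt(max(smoothed_sd**2 - bandwidth**2, 1e-4)))

    lo, hi = search_window
    window = (np.exp(grid) >= lo * peak_2n) & (np.exp(grid) <= hi * peak_2n)
    cand = [m for m in modes if window[m] and m != i2n]
    if cand:
        i4n = cand[int(np.argmax(dens[cand]))]
        peak_4n = float(np.exp(grid[i4n]))
        g1_upper = peak_2n * (1.0 + cv_multiplier * cv_hat)
        s_upper = peak_4n * (1.0 - cv_multiplier * cv_hat)
        method = {"mode": "kde", "cv_hat": cv_hat}
        if not (peak_2n < g1_upper < s_upper):  # pathological CV; fall back
            g1_upper = FALLBACK_G1_UPPER * peak_2n
            s_upper = FALLBACK_S_UPPER * peak_2n
            method = {"mode": "fallback", "reason": "gate_overlap", "cv_hat": cv_hat}
    else:
        warnings.warn(
            "no 4N mode found; falling back to fixed gate multipliers",
            DegenerateDistributionWarning,
        )
        peak_4n = 2.0 * peak_2n
        g1_upper = FALLBACK_G1_UPPER * peak_2n
        s_upper = FALLBACK_S_UPPER * peak_2n
        method = {"mode": "fallback", "reason": "no_4n_mode", "cv_hat": cv_hat}

    gates = PhaseGates(
        peak_2n=peak_2n, peak_4n=peak_4n, g1_upper=g1_upper, s_upper=s_upper, method=method
    )
    gates.validate()
    return gates


def classify_dna(values: np.ndarray, gates: PhaseGates) -> np.ndarray:
    """Vectorized phase call: <= g1_upper -> G1; > s_upper -> G2M; else S."""
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, "S", dtype=object)
    out[values <= gates.g1_upper] = "G1"
    out[values > gates.s_upper] = "G2M"
    return out


def assign_phase(
    records: Sequence[CellRecord] | pd.DataFrame, gates: PhaseGates
) -> Sequence[CellRecord] | pd.DataFrame:
    """Assign a phase to every record (total, deterministic).

    Accepts a list of :class:`CellRecord` (mutated in place) or a DataFrame
    with an ``integrated_dna`` column (phase column written).
    """
    gates.validate()
    if isinstance(records, pd.DataFrame):
        records = records.copy()
        records["phase"] = classify_dna(records["integrated_dna"].to_numpy(), gates)
        return records
    for r in records:
        r.phase = str(classify_dna(np.array([r.integrated_dna]), gates)[0])
    return records


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .spots import records_table

    return records_table(records)


def phase_peroxisome_profile(records) -> dict[str, float]:
    """Per-phase mean spot total intensity normalized to the G1 mean.

    The G1 entry is exactly 1; a phase with no cells reports NaN (missing,
    not zero).
    """
    df = _records_frame(records)
    means = df.groupby("phase")["spot_total_intensity"].mean()
    if "G1" not in means or not np.isfinite(means["G1"]) or means["G1"] == 0:
        raise ValueError("cannot normalize: no G1 cells or zero G1 mean")
    g1 = means["G1"]
    out = {}
    for ph in PHASES:
        out[ph] = float(means[ph] / g1) if ph in means.index else float("nan")
    out["G1"] = 1.0
    return out


def arrest_experiment_report(
    condition_records: Mapping[str, Sequence[CellRecord] | pd.DataFrame],
    control: str = "control",
    shared_gates: bool = True,
    min_cells: int = 200,
) -> pd.DataFrame:
    """Phase fractions and control-normalized peroxisome intensity per condition.

    Gates are fit on the control population and, by default, applied to all
    conditions so arrest compounds do not distort their own gates
    (``shared_gates=False`` refits per condition).  Peroxisome intensity is
    each condition's mean spot total intensity divided by the control mean.
    """
    if control not in condition_records:
        raise ValueError(f"missing control condition {control!r}")
    ctrl_df = _records_frame(condition_records[control])
    control_gates = fit_dna_gates(ctrl_df["integrated_dna"].to_numpy(), min_cells=min_cells)
    ctrl_mean = float(ctrl_df["spot_total_intensity"].mean())
    if ctrl_mean == 0:
        raise ValueError("control mean spot intensity is zero")

    rows = []
    for cond, recs in condition_records.items():
        df = _records_frame(recs)
        gates = control_gates
        if not shared_gates and cond != control:
            gates = fit_dna_gates(df["integrated_dna"].to_numpy(), min_cells=min_cells)
        phases = classify_dna(df["integrated_dna"].to_numpy(), gates)
        n = len(df)
        row = {"condition": cond, "n_cells": n}
        for ph in PHASES:
            row[f"frac_{ph}"] = float(np.mean(phases == ph)) if n else np.nan
        row["norm_peroxisome"] = float(df["spot_total_intensity"].mean() / ctrl_mean)
        rows.append(row)
    return pd.DataFrame(rows)


def gates_to_dict(gates: PhaseGates) -> dict:
    return {
        "peak_2n": gates.peak_2n,
        "peak_4n": gates.peak_4n,
        "g1_upper": gates.g1_upper,
        "s_upper": gates.s_upper,
        "method": gates.method,
    }


def gates_from_dict(d: dict) -> PhaseGates:
    return PhaseGates(
        peak_2n=d["peak_2n"],
        peak_4n=d["peak_4n"],
        g1_upper=d["g1_upper"],
        s_upper=d["s_upper"],
        method=dict(d.get("method", {})),
    )
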
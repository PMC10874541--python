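"""Flow-cytometry-style analyses: viability gating, ROS shifts, statistics.

Event tables are plain per-event DataFrames (columns among dna, peroxisome,
dcfda, pi).  Two-group comparisons use the unpaired Student's t test;
multi-group comparisons use one-way ANOVA with Tukey's post hoc test;
results are summarized as mean +/- standard deviation and called
significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cellcycle import fit_dna_gates, classify_dna, phase_peroxisome_profile

ALPHA = 0.05

SYNERGY_CONDITIONS = (
    "control",
    "inducer",
    "chemical",
    "combination",
    "combination_inhibitor",
)


@dataclass
class ComparisonResult:
    """Group comparison summary (mean +/- SD, statistic, p-values)."""

    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    test: str  # "t_test" | "anova_tukey"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # Tukey table when test == anova_tukey

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _require_column(events: pd.DataFrame, col: str) -> np.ndarray:
    if col not in events.columns:
        raise ValueError(f"events table lacks a {col!r} column")
    return events[col].to_numpy(dtype=float)


def auto_pi_threshold(pi: np.ndarray, control_pi: np.ndarray | None = None) -> float:
    """Valley between the two modes of the log-PI density.

    Falls back to the 99.5th percentile of a designated unstained/untreated
    control when the distribution is unimodal; raises if neither works.
    """
    logp = np.log(np.clip(pi, 1e-12, None))
    kde = stats.gaussian_kde(logp, bw_method="silverman")
    grid = np.linspace(logp.min(), logp.max(), 512)
    dens = kde(grid)
    peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    # keep modes that are not negligible shoulders
    peaks = [p for p in peaks if dens[p] > 0.02 * dens.max()]
    if len(peaks) >= 2:
        top2 = sorted(sorted(peaks, key=lambda p: dens[p], reverse=True)[:2])
        valley = top2[0] + int(np.argmin(dens[top2[0] : top2[1] + 1]))
        return float(np.exp(grid[valley]))
    if control_pi is not None:
        return float(np.percentile(control_pi, 99.5))
    raise ValueError("PI distribution is unimodal and no control sample was given")


def gate_pi_positive(
    events: pd.DataFrame,
    threshold: float | str = "auto",
    control_events: pd.DataFrame | None = None,
) -> float:
    """Fraction of PI-positive (dead) events: pi > threshold."""
    pi = _require_column(events, "pi")
    if threshold == "auto":
        ctrl = _require_column(control_events, "pi") if control_events is not None else None
        threshold = auto_pi_threshold(pi, ctrl)
    return float(np.mean(pi > float(threshold)))


def quantify_ros_shift(treated_events: pd.DataFrame, control_events: pd.DataFrame,
                       statistic: str = "median") -> float:
    """Relative ROS level: treated / control DCFDA summary (median by default)."""
    t = _require_column(treated_events, "dcfda")
    c = _require_column(control_events, "dcfda")
    summ = np.median if statistic == "median" else np.mean
    denom = float(summ(c))
    if denom == 0:
        raise ValueError("control DCFDA summary is zero")
    return float(summ(t)) / denom


def flow_phase_peroxisome(
    events: pd.DataFrame, min_cells: int = 200, cv_multiplier: float = 2.5
) -> dict[str, float]:
    """Per-phase peroxisome means normalized to G1, gated on the dna column.

    Uses stricter (wider-margin) gate boundaries than phase-fraction
    estimation: for expression profiling, purity of each phase population
    matters more than assigning every event.
    """
    dna = _require_column(events, "dna")
    _require_column(events, "peroxisome")
    gates = fit_dna_gates(dna, min_cells=min_cells, cv_multiplier=cv_multiplier)
    df = pd.DataFrame(
        {
            "phase": classify_dna(dna, gates),
            "spot_total_intensity": events["peroxisome"].to_numpy(dtype=float),
        }
    )
    return phase_peroxisome_profile(df)


def compare_conditions(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """Unpaired Student's t test (2 groups) or one-way ANOVA + Tukey (>2).

    Degenerate case: all groups identical with zero variance reports
    statistic 0 and p = 1.  Any group with fewer than 2 values raises.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    means = {k: float(a.mean()) for k, a in arrays.items()}
    sds = {k: float(a.std(ddof=1)) for k, a in arrays.items()}

    all_vals = np.concatenate(list(arrays.values()))
    degenerate = np.ptp(all_vals) == 0.0

    if len(names) == 2:
        if degenerate:
            return ComparisonResult(names, means, sds, "t_test", 0.0, 1.0)
        stat, p = stats.ttest_ind(arrays[names[0]], arrays[names[1]], equal_var=True)
        return ComparisonResult(names, means, sds, "t_test", float(stat), float(p))

    if degenerate:
        return ComparisonResult(names, means, sds, "anova_tukey", 0.0, 1.0,
                                pairwise=_degenerate_tukey(names))
    stat, p = stats.f_oneway(*arrays.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([arrays[k] for k in names])
    labels = np.concatenate([[k] * len(arrays[k]) for k in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return ComparisonResult(
        names, means, sds, "anova_tukey", float(stat), float(p), pairwise=pairwise
    )


def _degenerate_tukey(names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append({"group1": a, "group2": b, "meandiff": 0.0,
                         "p-adj": 1.0, "reject": False})
    return pd.DataFrame(rows)


def tukey_pair_p(pairwise: pd.DataFrame, a: str, b: str) -> float:
    """Adjusted p-value for an unordered group pair from a Tukey table."""
    m = pairwise[
        ((pairwise["group1"] == a) & (pairwise["group2"] == b))
        | ((pairwise["group1"] == b) & (pairwise["group2"] == a))
    ]
    if m.empty:
        raise KeyError(f"pair ({a}, {b}) not in Tukey table")
    return float(m["p-adj"].iloc[0])


@dataclass
class SynergyReport:
    """Contrast results for the combination-treatment design."""

    overall: ComparisonResult
    contrasts: dict[str, float] = field(default_factory=dict)  # name -> adjusted p

    def contrast_significant(self, name: str) -> bool:
        return self.contrasts[name] < ALPHA


def synergy_report(death_fractions: Mapping[str, Sequence[float]]) -> SynergyReport:
    """Compare the combination-design death fractions across conditions.

    Requires replicate death-fraction values for control, inducer alone,
    chemical alone, combination, and combination plus inhibitor.  Runs the
    overall ANOVA + Tukey and extracts the contrasts of interest:
    combination vs each single agent, combination vs the rescued condition,
    and rescue vs control.
    """
    missing = [c for c in SYNERGY_CONDITIONS if c not in death_fractions]
    if missing:
        raise ValueError(f"missing required conditions: {missing}")
    overall = compare_conditions({k: death_fractions[k] for k in SYNERGY_CONDITIONS})
    pw = overall.pairwise
    contrasts = {
        "combination_vs_inducer": tukey_pair_p(pw, "combination", "inducer"),
        "combination_vs_chemical": tukey_pair_p(pw, "combination", "chemical"),
        "combination_vs_rescue": tukey_pair_p(pw, "combination", "combination_inhibitor"),
        "rescue_vs_control": tukey_pair_p(pw, "combination_inhibitor", "control"),
    }
    return SynergyReport(overall=overall, contrasts=contrasts)
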
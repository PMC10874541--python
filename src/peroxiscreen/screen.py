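"""Well/compound aggregation, cytotoxicity filter, and percentile hit calling.

Per-cell records are averaged per well, wells whose compound depresses the
cell count below 25% of the control average are excluded as cytotoxic, the
remaining compounds are standardized per replicate to the control mean and
replicate-averaged, and the 5th/95th percentiles of the standardized cloud
set the bands that categorize compounds into groups A (cell-cycle driven),
B (peroxisome up) and C (peroxisome down).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CYTOTOX_CELL_COUNT_FRACTION = 0.25
PERCENTILE_LOW = 5.0
PERCENTILE_HIGH = 95.0

METRIC_COLUMNS = {
    "std_peroxisome": "mean_spot_total_intensity",
    "std_dna": "mean_integrated_dna",
    "rel_cell_count": "cell_count",
    "rel_spot_count": "mean_spot_count",
}


@dataclass
class WellSummary:
    """Aggregates over the retained single cells of one well."""

    well_id: str
    compound_id: str
    replicate: int
    cell_count: int
    mean_spot_count: float
    mean_spot_total_intensity: float
    mean_integrated_dna: float


@dataclass
class CutoffPair:
    """5th/95th percentile band for one standardized axis."""

    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"cutoffs must satisfy low < high, got {self.low} >= {self.high}")

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass
class CompoundResult:
    """Replicate-averaged fold-of-control values and category for one compound."""

    compound_id: str
    std_peroxisome: float
    std_dna: float
    rel_cell_count: float
    rel_spot_count: float
    cytotoxic: bool = False
    category: str = "none"  # A | B | C | none | excluded


def summarize_well(records: pd.DataFrame, well_id=None, compound_id="", replicate=0) -> WellSummary:
    """Arithmetic means over the retained cells of one well.

    An empty input yields ``cell_count`` 0 with NaN means (undefined).
    """
    if len(records) and records["well_id"].nunique() > 1:
        raise ValueError("records span multiple wells")
    if well_id is None:
        well_id = records["well_id"].iloc[0] if len(records) else ""
    n = len(records)
    return WellSummary(
        well_id=str(well_id),
        compound_id=str(compound_id),
        replicate=int(replicate),
        cell_count=n,
        mean_spot_count=float(records["spot_count"].mean()) if n else float("nan"),
        mean_spot_total_intensity=(
            float(records["spot_total_intensity"].mean()) if n else float("nan")
        ),
        mean_integrated_dna=float(records["integrated_dna"].mean()) if n else float("nan"),
    )


def summarize_wells(cells: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Well-level summary table for all wells in the plate map.

    Wells without any retained cell keep ``cell_count`` 0 and NaN means.
    """
    required = {"well_id", "compound_id", "replicate", "role"}
    missing = required - set(plate_map.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    agg = (
        cells.groupby("well_id")
        .agg(
            cell_count=("cell_label", "size"),
            mean_spot_count=("spot_count", "mean"),
            mean_spot_total_intensity=("spot_total_intensity", "mean"),
            mean_integrated_dna=("integrated_dna", "mean"),
        )
        .reset_index()
    )
    out = plate_map.merge(agg, on="well_id", how="left")
    out["cell_count"] = out["cell_count"].fillna(0).astype(int)
    return out


def apply_cytotoxicity_filter(well_summaries: pd.DataFrame) -> pd.DataFrame:
    """Flag cytotoxic compounds by the strict 25%-of-control cell-count rule.

    The control average is the mean cell count over control wells (averaged
    per replicate first); a compound is cytotoxic when its replicate-mean
    cell count is strictly below 25% of that average.  Wells with zero
    cells mark their compound cytotoxic regardless.
    """
    df = well_summaries.copy()
    controls = df[df["role"] == "control"]
    if controls.empty:
        raise ValueError("no control wells in plate map")
    control_avg = float(controls.groupby("replicate")["cell_count"].mean().mean())
    comp_means = df[df["role"] == "compound"].groupby("compound_id")["cell_count"].mean()
    zero_wells = df[(df["role"] == "compound") & (df["cell_count"] == 0)]["compound_id"]
    cytotoxic = set(
        comp_means[comp_means < CYTOTOX_CELL_COUNT_FRACTION * control_avg].index
    ) | set(zero_wells)
    df["cytotoxic"] = df["compound_id"].isin(cytotoxic) & (df["role"] == "compound")
    df.attrs["control_average_cell_count"] = control_avg
    return df


def standardize_to_control(well_summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-compound fold-of-control values, standardized within replicates.

    Within each replicate every metric is divided by that replicate's
    control-well mean; compound-level values are the mean over replicates.
    Cytotoxic compounds (if flagged) are excluded from the output.
    """
    df = well_summaries.copy()
    if "cytotoxic" not in df.columns:
        df["cytotoxic"] = False
    controls = df[df["role"] == "control"]
    if controls.empty:
        raise ValueError("no control wells")
    ctrl = controls.groupby("replicate")[list(METRIC_COLUMNS.values())].mean()
    if (ctrl <= 0).any().any():
        raise ValueError("control means must be positive")
    comp = df[(df["role"] == "compound") & (~df["cytotoxic"]) & (df["cell_count"] > 0)].copy()
    for out_col, src_col in METRIC_COLUMNS.items():
        comp[out_col] = comp[src_col] / comp["replicate"].map(ctrl[src_col]).astype(float)
    result = (
        comp.groupby("compound_id")[list(METRIC_COLUMNS)].mean().reset_index()
    )
    return result


def compute_cutoffs(values: Sequence[float], min_values: int = 20) -> CutoffPair:
    """Empirical 5th/95th percentile cutoffs (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_values:
        raise ValueError(f"need at least {min_values} values, got {len(arr)}")
    low = float(np.percentile(arr, PERCENTILE_LOW, method="linear"))
    high = float(np.percentile(arr, PERCENTILE_HIGH, method="linear"))
    return CutoffPair(low=low, high=high)


def categorize_compounds(
    std_values: pd.DataFrame,
    cutoffs_perox: CutoffPair,
    cutoffs_dna: CutoffPair,
) -> pd.DataFrame:
    """Assign A/B/C categories from the two standardized axes.

    A: DNA above band (cell-cycle driven change).  B: peroxisome above band
    with DNA in band.  C: peroxisome below band with DNA in band.  Anything
    else, including sub-band DNA, is "none".
    """
    df = std_values.copy()
    perox = df["std_peroxisome"].to_numpy(dtype=float)
    dna = df["std_dna"].to_numpy(dtype=float)
    dna_in_band = (dna >= cutoffs_dna.low) & (dna <= cutoffs_dna.high)
    cat = np.full(len(df), "none", dtype=object)
    cat[dna > cutoffs_dna.high] = "A"
    cat[(perox > cutoffs_perox.high) & dna_in_band] = "B"
    cat[(perox < cutoffs_perox.low) & dna_in_band] = "C"
    df["category"] = cat
    return df


def build_heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Fold-of-control metric table for categorized (A/B/C) compounds.

    One row per hit with the four fold-of-control metrics, sorted by
    category then standardized peroxisome signal.
    """
    cols = ["compound_id", "category", "rel_cell_count", "rel_spot_count",
            "std_peroxisome", "std_dna"]
    hits = results[results["category"].isin(["A", "B", "C"])]
    return (
        hits[cols]
        .sort_values(["category", "std_peroxisome"], ascending=[True, False])
        .reset_index(drop=True)
    )


def analyze_screen(
    cells: pd.DataFrame, plate_map: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, CutoffPair]]:
    """Full screen analysis from a per-cell table and plate map.

    Returns the compound-result table (including cytotoxic compounds marked
    "excluded") and the per-axis cutoffs used.
    """
    wells = summarize_wells(cells, plate_map)
    wells = apply_cytotoxicity_filter(wells)
    std = standardize_to_control(wells)
    cut_perox = compute_cutoffs(std["std_peroxisome"])
    cut_dna = compute_cutoffs(std["std_dna"])
    results = categorize_compounds(std, cut_perox, cut_dna)
    results["cytotoxic"] = False

    cyto_ids = sorted(
        set(wells.loc[wells["cytotoxic"], "compound_id"]) - set(results["compound_id"])
    )
    if cyto_ids:
        excluded = pd.DataFrame(
            {
                "compound_id": cyto_ids,
                "std_peroxisome": np.nan,
                "std_dna": np.nan,
                "rel_cell_count": np.nan,
                "rel_spot_count": np.nan,
                "category": "excluded",
                "cytotoxic": True,
            }
        )
        results = pd.concat([results, excluded], ignore_index=True)
    results = results.sort_values("compound_id").reset_index(drop=True)
    return results, {"peroxisome": cut_perox, "dna": cut_dna}
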
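"""End-to-end orchestration: simulate -> segment -> quantify -> gate -> categorize.

A single :class:`RunConfig` drives the whole run; one top-level seed fans
out to per-stage child seeds by stable hashing so adding a stage never
reshuffles earlier ones.  All outputs are plain CSV/JSON (plus TIFF for
image fidelity) written atomically, with a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cellcycle import assign_phase, fit_dna_gates, gates_to_dict, phase_peroxisome_profile
from .screen import analyze_screen, build_heatmap_table
from .segmentation import SegmentationParams, segment_field
from .spots import SpotParams, detect_spots, records_table, summarize_cells
from .synthetic import (
    ARCHETYPES,
    SceneSpec,
    make_effect,
    render_field,
    simulate_screen,
)


@dataclass
class SimulationConfig:
    """What to simulate when no real images are supplied."""

    n_replicates: int = 3
    cells_per_well: int = 2000
    n_fields: int = 12
    archetype_counts: dict = field(
        default_factory=lambda: {
            "A_cell_cycle": 4,
            "B_perox_up": 4,
            "C_perox_down": 4,
            "cytotoxic": 2,
            "null": 82,
        }
    )
    scene: dict = field(default_factory=dict)  # SceneSpec overrides

    def n_compounds(self) -> int:
        return int(sum(self.archetype_counts.values()))

    def validate(self) -> None:
        for k in self.archetype_counts:
            if k not in ARCHETYPES:
                raise ValueError(f"simulation.archetype_counts: unknown archetype {k!r}")
        if self.n_replicates < 1:
            raise ValueError("simulation.n_replicates must be >= 1")


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    output_dir: str = "peroxiscreen_out"
    seed: int = 0
    fidelity: str = "table"  # "table" | "image"
    plate_map: str | None = None  # CSV path (required for real images)
    images_dir: str | None = None  # directory of <well>_f<idx>.tif fields
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    segmentation: dict = field(default_factory=dict)  # SegmentationParams overrides
    spot: dict = field(default_factory=dict)  # SpotParams overrides
    gating: dict = field(default_factory=lambda: {"min_cells": 200})

    def validate(self) -> None:
        if self.fidelity not in ("table", "image"):
            raise ValueError("fidelity: must be 'table' or 'image'")
        if self.simulation is None:
            if self.plate_map is None:
                raise ValueError("plate_map: required when no simulation is configured")
            if self.images_dir is None:
                raise ValueError("images_dir: required when no simulation is configured")
        else:
            self.simulation.validate()
        SegmentationParams(**self.segmentation)
        SpotParams(**self.spot)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        io.atomic_write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**31 - 1)


def _effects_from_counts(counts: dict) -> list:
    effects = []
    i = 0
    for archetype, n in counts.items():
        for _ in range(int(n)):
            effects.append(make_effect(f"cmpd{i:04d}", archetype))
            i += 1
    return effects


def quantify_field(
    dna: np.ndarray,
    reporter: np.ndarray,
    seg_params: SegmentationParams,
    spot_params: SpotParams,
    well_id: str = "",
    field_index: int = 0,
) -> pd.DataFrame:
    """Segment one field and measure its cells; empty table if all excluded."""
    nuclei, _, comp = segment_field(dna, seg_params, well_id, field_index)
    if comp is None:
        return records_table([])
    spots = detect_spots(reporter, comp, spot_params)
    return records_table(summarize_cells(nuclei, comp, spots, dna, reporter))


def _cells_from_images(dataset, seg_params, spot_params) -> pd.DataFrame:
    frames = []
    for well_id, fields in dataset.images.items():
        for f_idx, fld in enumerate(fields):
            frames.append(
                quantify_field(fld.dna, fld.reporter, seg_params, spot_params, well_id, f_idx)
            )
    if not frames:
        return records_table([])
    df = pd.concat(frames, ignore_index=True)
    df["cell_label"] = np.arange(1, len(df) + 1)  # unique within well across fields
    return df


def run_screen(config: RunConfig) -> dict:
    """Run the full screen and write the output bundle.

    Outputs (under ``config.output_dir``): cells.csv, wells implicit in
    compounds.csv, compounds.csv, heatmap_table.csv, gates.json,
    phase_profile.json, manifest.json, and (when matplotlib succeeds)
    screen_scatter.png.  Deterministic given the config.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_params = SegmentationParams(**config.segmentation)
    spot_params = SpotParams(**config.spot)

    if config.simulation is not None:
        sim = config.simulation
        scene = SceneSpec(**sim.scene) if sim.scene else SceneSpec()
        effects = _effects_from_counts(sim.archetype_counts)
        dataset = simulate_screen(
            n_compounds=len(effects),
            effects=effects,
            n_replicates=sim.n_replicates,
            fidelity=config.fidelity,
            base_spec=scene,
            seed=stage_seed(config.seed, "simulate"),
            n_fields=sim.n_fields,
            cells_per_well=sim.cells_per_well,
        )
        plate_map = dataset.plate_map
        if config.fidelity == "table":
            cells = dataset.cells
        else:
            cells = _cells_from_images(dataset, seg_params, spot_params)
        io.write_csv(dataset.truth, out / "truth.csv")
    else:
        plate_map = pd.read_csv(config.plate_map)
        frames = []
        for _, row in plate_map.iterrows():
            pattern = f"{row['well_id']}_f*.tif"
            for path in sorted(Path(config.images_dir).glob(pattern)):
                f_idx = int(path.stem.rsplit("_f", 1)[1])
                dna, reporter = io.read_field_tiff(path)
                frames.append(
                    quantify_field(dna, reporter, seg_params, spot_params,
                                   str(row["well_id"]), f_idx)
                )
        if not frames:
            raise FileNotFoundError(f"no field TIFFs found under {config.images_dir}")
        cells = pd.concat(frames, ignore_index=True)

    # gate on control cells only, then apply plate-wide
    control_wells = plate_map.loc[plate_map["role"] == "control", "well_id"]
    ctrl_cells = cells[cells["well_id"].isin(control_wells)]
    gates = fit_dna_gates(
        ctrl_cells["integrated_dna"].to_numpy(), min_cells=config.gating.get("min_cells", 200)
    )
    cells = assign_phase(cells, gates)
    profile = phase_peroxisome_profile(cells[cells["well_id"].isin(control_wells)])

    results, cutoffs = analyze_screen(cells, plate_map)
    heatmap = build_heatmap_table(results)

    io.write_csv(cells, out / "cells.csv")
    io.write_csv(results, out / "compounds.csv")
    io.write_csv(heatmap, out / "heatmap_table.csv")
    io.write_json(gates_to_dict(gates), out / "gates.json")
    io.write_json(profile, out / "phase_profile.json")
    io.write_json(
        {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "n_cells": int(len(cells)),
            "n_compounds": int((results["category"] != "excluded").sum()),
            "n_excluded": int((results["category"] == "excluded").sum()),
            "cutoffs": {
                axis: {"low": c.low, "high": c.high} for axis, c in cutoffs.items()
            },
        },
        out / "manifest.json",
    )
    _screen_scatter_plot(results, cutoffs, out / "screen_scatter.png")
    return {
        "cells": cells,
        "results": results,
        "cutoffs": cutoffs,
        "gates": gates,
        "profile": profile,
        "output_dir": str(out),
    }


def _screen_scatter_plot(results, cutoffs, path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    ok = results[results["category"] != "excluded"]
    colors = {"A": "tab:orange", "B": "tab:red", "C": "tab:blue", "none": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, sub in ok.groupby("category"):
        ax.scatter(sub["std_dna"], sub["std_peroxisome"], s=12,
                   c=colors.get(cat, "k"), label=cat)
    for v in (cutoffs["dna"].low, cutoffs["dna"].high):
        ax.axvline(v, ls="--", c="k", lw=0.8)
    for v in (cutoffs["peroxisome"].low, cutoffs["peroxisome"].high):
        ax.axhline(v, ls="--", c="k", lw=0.8)
    ax.set_xlabel("standardized DNA signal (fold of control)")
    ax.set_ylabel("standardized peroxisome signal (fold of control)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_demo(seed: int = 0, output_dir: str = "peroxiscreen_demo") -> dict:
    """Small end-to-end example: 4 image wells plus a 96-compound table screen.

    Renders a handful of fields through the full imaging path, runs the
    table-fidelity screen, and writes per-phase profile bars, a single-cell
    scatter, and the categorized screen scatter.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # imaging path: 4 wells x 2 small fields
    scene = SceneSpec(
        image_height=360,
        image_width=360,
        n_cells=60,
        cluster_fraction=0.05,
        edge_fraction=0.05,
    )
    seg_params = SegmentationParams()
    spot_params = SpotParams(sigma=scene.spot_sigma_px)
    frames = []
    rng = np.random.default_rng(stage_seed(seed, "demo-images"))
    for w in range(4):
        well_id = f"demo{w}"
        for f_idx in range(2):
            fld = render_field(replace(scene, seed=int(rng.integers(0, 2**31 - 1))))
            io.write_field_tiff(out / f"{well_id}_f{f_idx:02d}.tif", fld.dna, fld.reporter)
            frames.append(
                quantify_field(fld.dna, fld.reporter, seg_params, spot_params, well_id, f_idx)
            )
    image_cells = pd.concat(frames, ignore_index=True)
    gates = fit_dna_gates(image_cells["integrated_dna"].to_numpy(), min_cells=100)
    image_cells = assign_phase(image_cells, gates)
    profile = phase_peroxisome_profile(image_cells)
    io.write_csv(image_cells, out / "demo_image_cells.csv")

    # table-fidelity 96-compound screen
    config = RunConfig(
        output_dir=str(out / "screen"),
        seed=seed,
        fidelity="table",
        simulation=SimulationConfig(cells_per_well=500),
    )
    screen_out = run_screen(config)

    _demo_plots(image_cells, profile, out)
    return {
        "image_cells": image_cells,
        "gates": gates,
        "profile": profile,
        "screen": screen_out,
        "output_dir": str(out),
    }


def _demo_plots(cells, profile, out: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for phase, sub in cells.groupby("phase"):
        axes[0].scatter(sub["integrated_dna"], sub["spot_total_intensity"], s=6, label=phase)
    axes[0].set_xlabel("integrated DNA signal")
    axes[0].set_ylabel("spot total intensity / cell")
    axes[0].legend(frameon=False, fontsize=8)
    phases = ["G1", "S", "G2M"]
    axes[1].bar(phases, [profile[p] for p in phases], color="0.4")
    axes[1].set_ylabel("peroxisome intensity (G1-normalized)")
    fig.tight_layout()
    fig.savefig(out / "demo_report.png", dpi=150)
    plt.close(fig)
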
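# peroxiscreen

A tested, reusable re-implementation of a high-content image-screening
analysis for chemical modulators of peroxisomal abundance. The pipeline
covers single-cell nuclear segmentation with a simulated-cytoplasm
compartment, punctate spot quantification, DNA-content cell-cycle gating,
percent-of-control compound categorization, and flow-cytometry-style event
analyses — all exercised end to end on a bundled ground-truthed synthetic
data generator, so no external data are required.

## Modules

| module                      | what it does |
|-----------------------------|--------------|
| `peroxiscreen.synthetic`    | Ground-truthed two-channel field renderer, plate-scale screen simulator (table or image fidelity), flow-event simulator. Deterministic per seed. |
| `peroxiscreen.segmentation` | Nucleus detection (smoothed log-Otsu threshold), edge/cluster exclusion flags, seeded nearest-nucleus cytoplasm partition. |
| `peroxiscreen.spots`        | LoG band-pass spot detection restricted to cytoplasm, per-spot intensity integration with nearest-peak pixel partitioning, per-cell records. |
| `peroxiscreen.cellcycle`    | 2N/4N mode finding on the DNA-content histogram, G1/S/G2-M gate boundaries, per-phase G1-normalized peroxisome profiles, arrest reports. |
| `peroxiscreen.screen`       | Well summaries, strict 25%-of-control cytotoxicity filter, per-replicate standardization, 5/95-percentile cutoffs, A/B/C categorization, heatmap table. |
| `peroxiscreen.flow`         | PI-positive death gating (auto valley threshold), DCFDA ROS fold, per-phase flow profiles, Student's t / ANOVA+Tukey comparisons, synergy contrasts. |
| `peroxiscreen.pipeline`     | `RunConfig` (YAML), end-to-end `run_screen`, `run_demo`, deterministic seed fan-out, output bundle with manifest. |

## CLI

```bash
peroxiscreen simulate --out simulated --seed 1        # write a synthetic dataset
peroxiscreen segment simulated/w0_f00.tif --out seg/  # nuclei labels + table
peroxiscreen quantify simulated/w0_f00.tif --out cells.csv
peroxiscreen gate cells.csv --out gates.json          # DNA-content phase gates
peroxiscreen screen --config config.yaml              # full screen analysis
peroxiscreen flow pi events.csv                       # PI+ death fraction
peroxiscreen flow ros treated.csv control.csv         # relative ROS level
peroxiscreen demo --seed 1 --out demo_out             # small end-to-end example
```

A minimal screen config:

```yaml
output_dir: screen_out
seed: 1
fidelity: table          # or "image" to render and re-segment fields
simulation:
  n_replicates: 3
  cells_per_well: 2000
  archetype_counts: {A_cell_cycle: 4, B_perox_up: 4, C_perox_down: 4,
                     cytotoxic: 2, "null": 82}
```

`run_screen` writes `cells.csv`, `compounds.csv`, `heatmap_table.csv`,
`gates.json`, `phase_profile.json`, a categorized scatter plot, and a
`manifest.json` with the config hash; repeated runs with the same config
are byte-identical.

## Notes

- All outputs are plain CSV/JSON; images are float32 multi-page TIFF
  (page 0 = DNA channel, page 1 = reporter channel).
- Library-scale screens use the table-fidelity fast path (per-cell tables
  straight from the generative model); the imaging path is exercised on
  demo-scale subsets and in the test suite.
- Scratch output lands under `scratch/` (ignored).
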
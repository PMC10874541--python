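"""Ground-truthed synthetic data: two-channel fields, plate screens, flow events.

Every generator is a pure function of its spec (including the seed), so
repeated calls are bit-identical.  Images carry a DNA channel (elliptical
nuclei whose integrated signal is proportional to DNA content) and a
reporter channel (isotropic Gaussian puncta in a perinuclear zone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

PHASES = ("G1", "S", "G2M")

ARCHETYPES = ("A_cell_cycle", "B_perox_up", "C_perox_down", "cytotoxic", "null")

#: default effect magnitudes; free parameters chosen so planted effects
#: are recoverable downstream.
DEFAULT_ARCHETYPE_PARAMS = {
    "A_cell_cycle": {"phase_shift": (0.2, 0.2, 0.6)},
    "B_perox_up": {"perox_multiplier": 1.8},
    "C_perox_down": {"perox_multiplier": 0.5},
    "cytotoxic": {"survival_fraction": 0.15},
    "null": {},
}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for one imaged field."""

    image_height: int = 512
    image_width: int = 512
    n_cells: int = 150
    phase_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    dna_2n_mean: float = 50_000.0
    dna_cv: float = 0.05
    spot_rate_per_phase: tuple[float, float, float] = (10.0, 20.0, 22.0)
    spot_intensity_mean: float = 500.0
    spot_intensity_cv: float = 0.25
    spot_sigma_px: float = 1.5
    nucleus_radius_mean: float = 8.0
    nucleus_radius_cv: float = 0.08
    cytoplasm_extent_px: float = 15.0
    background_dna: float = 5.0
    background_rfp: float = 2.0
    noise_model: str = "none"  # "none" | "poisson_gaussian"
    read_sigma: float = 1.0
    cluster_fraction: float = 0.0
    edge_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if len(self.phase_fractions) != 3:
            raise ValueError("phase_fractions must have 3 entries")
        if any(f < 0 for f in self.phase_fractions):
            raise ValueError("phase_fractions must be non-negative")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"phase_fractions must sum to 1, got {sum(self.phase_fractions)}"
            )
        if any(r < 0 for r in self.spot_rate_per_phase):
            raise ValueError("spot rates must be non-negative")
        for name in (
            "dna_2n_mean",
            "dna_cv",
            "spot_intensity_mean",
            "nucleus_radius_mean",
            "nucleus_radius_cv",
            "cytoplasm_extent_px",
            "background_dna",
            "background_rfp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.spot_sigma_px <= 0:
            raise ValueError("spot_sigma_px must be positive")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if not (0.0 <= self.edge_fraction <= 1.0):
            raise ValueError("edge_fraction must lie in [0, 1]")
        if self.noise_model not in ("none", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class GroundTruthCell:
    """Per-cell generative truth for one synthetic field."""

    cell_id: int
    phase: str
    dna_content: float
    nucleus_center: tuple[float, float]  # (row, col)
    nucleus_axes: tuple[float, float]  # semi-axes (a, b), pixels
    nucleus_angle: float  # radians
    spot_positions: np.ndarray  # (n, 2) float, (row, col)
    spot_intensities: np.ndarray  # (n,) float
    clustered: bool = False
    edge: bool = False

    @property
    def spot_count(self) -> int:
        return len(self.spot_intensities)

    @property
    def spot_total_intensity(self) -> float:
        return float(np.sum(self.spot_intensities))


@dataclass(frozen=True)
class CompoundEffect:
    """One compound's planted effect on the generative model."""

    compound_id: str
    archetype: str = "null"
    perox_multiplier: float = 1.0
    phase_shift: tuple[float, float, float] | None = None
    survival_fraction: float = 1.0

    def validate(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.perox_multiplier <= 0:
            raise ValueError("perox_multiplier must be > 0")
        if not (0.0 < self.survival_fraction <= 1.0):
            raise ValueError("survival_fraction must lie in (0, 1]")
        if self.archetype == "null" and (
            self.perox_multiplier != 1.0 or self.phase_shift is not None
        ):
            raise ValueError("null archetype must not carry an effect")
        if self.phase_shift is not None:
            if abs(sum(self.phase_shift) - 1.0) > 1e-9:
                raise ValueError("phase_shift must sum to 1")


def make_effect(compound_id: str, archetype: str = "null", **overrides) -> CompoundEffect:
    """Build a :class:`CompoundEffect` using default archetype magnitudes."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    params = dict(DEFAULT_ARCHETYPE_PARAMS[archetype])
    params.update(overrides)
    eff = CompoundEffect(compound_id=compound_id, archetype=archetype, **params)
    eff.validate()
    return eff


@dataclass(frozen=True)
class FlowConditionSpec:
    """Generative parameters for one flow-cytometry condition."""

    condition_id: str
    n_events: int = 10_000
    dead_fraction: float = 0.0
    pi_live_mean: float = 100.0
    pi_dead_mean: float = 1000.0
    pi_cv: float = 0.30
    ros_fold: float = 1.0
    dcfda_mean: float = 100.0
    dcfda_cv: float = 0.40
    phase_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    perox_rate_per_phase: tuple[float, float, float] = (10.0, 20.0, 22.0)
    spot_intensity_mean: float = 50.0
    dna_2n_mean: float = 100.0
    dna_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ValueError("dead_fraction must lie in [0, 1]")
        if self.pi_dead_mean <= self.pi_live_mean:
            raise ValueError("pi_dead_mean must exceed pi_live_mean")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")


# ---------------------------------------------------------------------------
# random helpers
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean, cv: float, size) -> np.ndarray:
    """Lognormal draws with exact mean ``mean`` and coefficient of variation ``cv``."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return np.broadcast_to(mean, size).copy() if np.ndim(mean) == 0 else mean.copy()
    sigma2 = math.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _sample_dna_content(
    rng: np.random.Generator, phases: np.ndarray, dna_2n: float, cv: float
) -> np.ndarray:
    """2N/4N lognormal peaks with a uniform S-phase bridge sharing the same CV."""
    n = len(phases)
    dna = np.empty(n, dtype=float)
    g1 = phases == 0
    s = phases == 1
    g2 = phases == 2
    dna[g1] = _lognormal(rng, dna_2n, cv, int(g1.sum()))
    dna[g2] = _lognormal(rng, 2.0 * dna_2n, cv, int(g2.sum()))
    ns = int(s.sum())
    base = rng.uniform(dna_2n, 2.0 * dna_2n, size=ns)
    dna[s] = base * _lognormal(rng, 1.0, cv, ns)
    return dna


def _ellipse_boundary_radius(a: float, b: float, psi: np.ndarray) -> np.ndarray:
    # polar radius of an ellipse with semi-axes (a, b) in its own frame
    return a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)


# ---------------------------------------------------------------------------
# cell population sampling
# ---------------------------------------------------------------------------


def sample_cell_population(spec: SceneSpec) -> list[GroundTruthCell]:
    """Draw the ground-truth cells of one field.

    Phase labels follow ``phase_fractions``; DNA content is lognormal around
    2N (G1) and 4N (G2/M) with a uniform bridge for S; per-cell spot counts
    are Poisson with a phase-linked rate; designated fractions are placed as
    touching pairs (``clustered``) or border-overlapping (``edge``).
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    n = spec.n_cells
    if n == 0:
        return []

    phases = rng.choice(3, size=n, p=np.asarray(spec.phase_fractions, dtype=float))
    dna = _sample_dna_content(rng, phases, spec.dna_2n_mean, spec.dna_cv)
    radii = _lognormal(rng, spec.nucleus_radius_mean, spec.nucleus_radius_cv, n)
    # mild eccentricity around the sampled mean radius
    ecc = rng.uniform(0.75, 1.0, size=n)
    axes_a = radii / np.sqrt(ecc)
    axes_b = radii * np.sqrt(ecc)
    angles = rng.uniform(0.0, math.pi, size=n)

    h, w = spec.image_height, spec.image_width
    margin = spec.nucleus_radius_mean * 1.6 + spec.cytoplasm_extent_px + 2.0
    margin = min(margin, min(h, w) / 2.0 - 1.0)

    n_edge = int(round(spec.edge_fraction * n))
    n_cluster_pairs = int(round(spec.cluster_fraction * n / 2.0))
    order = rng.permutation(n)
    edge_ids = set(order[:n_edge].tolist())
    cluster_pool = [i for i in order if i not in edge_ids]
    cluster_pairs = [
        (cluster_pool[2 * k], cluster_pool[2 * k + 1])
        for k in range(min(n_cluster_pairs, len(cluster_pool) // 2))
    ]
    cluster_ids = {i for pair in cluster_pairs for i in pair}

    # clustered cells are drawn at or above the mean radius so the merged
    # object's area clearly exceeds the median-area exclusion criterion
    for i in cluster_ids:
        radii[i] = spec.nucleus_radius_mean * rng.uniform(1.0, 1.0 + spec.nucleus_radius_cv)
        axes_a[i] = radii[i] / np.sqrt(ecc[i])
        axes_b[i] = radii[i] * np.sqrt(ecc[i])

    # rejection sampling keeps unrelated nuclei from touching by accident;
    # only designated cluster pairs are allowed to overlap.  A coarse grid
    # hash keeps the neighbor checks O(1) per candidate.
    centers = np.empty((n, 2), dtype=float)
    gap = 8.0  # unrelated masks must stay separable after threshold dilation
    reach = axes_a  # worst-case extent: the semi-major axis
    bin_size = 2.0 * float(reach.max()) + gap
    grid: dict[tuple[int, int], list[int]] = {}

    def _bin(r, c):
        return int(r // bin_size), int(c // bin_size)

    def _far_enough(r, c, rad, skip=()):
        bi, bj = _bin(r, c)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for j in grid.get((bi + di, bj + dj), ()):
                    if j in skip:
                        continue
                    pr, pc = centers[j]
                    if (r - pr) ** 2 + (c - pc) ** 2 < (rad + reach[j] + gap) ** 2:
                        return False
        return True

    def _register(i):
        grid.setdefault(_bin(centers[i, 0], centers[i, 1]), []).append(i)

    usable0 = max((h - 2 * margin) * (w - 2 * margin), 1.0)
    overpacked_placement = (
        n * math.pi * float(np.mean(reach) + gap / 2.0) ** 2 > 0.45 * usable0
    )

    max_tries = 1 if overpacked_placement else 200
    for i in range(n):
        r_i = reach[i]
        for _ in range(max_tries):
            if i in edge_ids:
                side = rng.integers(4)
                off = rng.uniform(0.0, 0.6 * radii[i])  # center overlaps the border
                if side == 0:
                    cand = (off, rng.uniform(margin, w - margin))
                elif side == 1:
                    cand = (h - 1 - off, rng.uniform(margin, w - margin))
                elif side == 2:
                    cand = (rng.uniform(margin, h - margin), off)
                else:
                    cand = (rng.uniform(margin, h - margin), w - 1 - off)
            else:
                cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if _far_enough(cand[0], cand[1], r_i):
                break
        centers[i] = cand
        _register(i)
    # second member of each clustered pair sits close enough to merge
    for a, b in cluster_pairs:
        pos = None
        for attempt in range(100):
            # close enough that thresholded masks always merge, far enough
            # that the union stays visibly enlarged / dumbbell-shaped
            d = rng.uniform(0.92, 1.05) * (radii[a] + radii[b])
            if attempt < 50:
                theta = rng.uniform(0.0, 2.0 * math.pi)
            else:  # aim at the image center to escape the border
                theta = math.atan2(w / 2.0 - centers[a][1], h / 2.0 - centers[a][0])
                theta = theta + rng.uniform(-0.5, 0.5)
                theta = math.pi / 2.0 - theta  # sin/cos convention below
            cand = centers[a] + d * np.array([math.sin(theta), math.cos(theta)])
            in_bounds = (
                margin <= cand[0] <= h - margin and margin <= cand[1] <= w - margin
            )
            if in_bounds and _far_enough(cand[0], cand[1], reach[b], skip={a, b}):
                pos = cand
                break
        if pos is None:  # last resort: keep the pair geometry, ignore bounds
            pos = np.clip(cand, 1.0, [h - 2.0, w - 2.0])
        old_bin = _bin(centers[b, 0], centers[b, 1])
        if b in grid.get(old_bin, ()):
            grid[old_bin].remove(b)
        centers[b] = pos
        _register(b)

    # per-cell nearest neighbors, precomputed once for the spot ownership test
    if n > 1:
        from scipy.spatial import cKDTree

        k_nb = min(5, n)
        _, nb_idx = cKDTree(centers).query(centers, k=k_nb)
        neighbors = [
            [int(j) for j in row if int(j) != i] for i, row in enumerate(np.atleast_2d(nb_idx))
        ]
    else:
        neighbors = [[]]

    overpacked = overpacked_placement  # spot ownership checks are moot too

    cells: list[GroundTruthCell] = []
    for i in range(n):
        phase_i = int(phases[i])
        k = rng.poisson(spec.spot_rate_per_phase[phase_i])
        # 4 px clearance keeps spot peaks outside the thresholded nuclear
        # mask, which dilates ~2-3 px beyond the true ellipse
        lo_off = min(4.0, spec.cytoplasm_extent_px / 2.0)
        hi_off = max(spec.cytoplasm_extent_px - 1.0, lo_off + 0.5)
        cos_t, sin_t = math.cos(angles[i]), math.sin(angles[i])
        # ~3.7 sigma apart: close pairs below that are not resolvable at
        # the band-pass scale and would merge into one detection
        min_sep = 2.0 * spec.spot_sigma_px + 2.5
        accepted: list[tuple[float, float]] = []
        if overpacked:
            # geometry guarantees are moot; draw all positions vectorized
            psi = rng.uniform(0.0, 2.0 * math.pi, size=k)
            rho = _ellipse_boundary_radius(axes_a[i], axes_b[i], psi)
            offs = rng.uniform(lo_off, hi_off, size=k)
            dr = (rho + offs) * np.sin(psi)
            dc = (rho + offs) * np.cos(psi)
            rows = np.clip(centers[i, 0] + dr * cos_t + dc * sin_t, 0.0, h - 1.0)
            cols = np.clip(centers[i, 1] - dr * sin_t + dc * cos_t, 0.0, w - 1.0)
            accepted = list(zip(rows, cols))
        for _ in range(0 if overpacked else k):
            for _try in range(30):
                psi = rng.uniform(0.0, 2.0 * math.pi)
                rho = float(_ellipse_boundary_radius(axes_a[i], axes_b[i], np.array([psi]))[0])
                offset = rng.uniform(lo_off, hi_off)
                dr = (rho + offset) * math.sin(psi)
                dc = (rho + offset) * math.cos(psi)
                r_pos = centers[i, 0] + dr * cos_t + dc * sin_t
                c_pos = centers[i, 1] - dr * sin_t + dc * cos_t
                r_pos = min(max(r_pos, 0.0), h - 1.0)
                c_pos = min(max(c_pos, 0.0), w - 1.0)
                if any(
                    (r_pos - ar) ** 2 + (c_pos - ac) ** 2 < min_sep**2
                    for ar, ac in accepted
                ):
                    continue
                if overpacked:
                    break
                # ownership: the position must stay closer to its own nucleus
                # than to any neighbor, or compartmentalization reassigns it
                margin_ok = min(
                    (
                        math.hypot(r_pos - centers[j, 0], c_pos - centers[j, 1]) - radii[j]
                        for j in neighbors[i]
                    ),
                    default=math.inf,
                )
                if margin_ok >= offset + 2.0:
                    break
            accepted.append((r_pos, c_pos))
        pos = np.array(accepted) if accepted else np.empty((0, 2))
        intens = _lognormal(rng, spec.spot_intensity_mean, spec.spot_intensity_cv, k)
        cells.append(
            GroundTruthCell(
                cell_id=i,
                phase=PHASES[phase_i],
                dna_content=float(dna[i]),
                nucleus_center=(float(centers[i, 0]), float(centers[i, 1])),
                nucleus_axes=(float(axes_a[i]), float(axes_b[i])),
                nucleus_angle=float(angles[i]),
                spot_positions=pos,
                spot_intensities=np.asarray(intens, dtype=float),
                clustered=i in cluster_ids,
                edge=i in edge_ids,
            )
        )
    return cells


def ground_truth_table(cells: Sequence[GroundTruthCell]) -> pd.DataFrame:
    """Flatten ground-truth cells into one row per cell."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "phase": [c.phase for c in cells],
            "dna_content": [c.dna_content for c in cells],
            "center_row": [c.nucleus_center[0] for c in cells],
            "center_col": [c.nucleus_center[1] for c in cells],
            "spot_count": [c.spot_count for c in cells],
            "spot_total_intensity": [c.spot_total_intensity for c in cells],
            "clustered": [c.clustered for c in cells],
            "edge": [c.edge for c in cells],
        }
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderedField:
    """A rendered two-channel field plus its per-cell ground truth."""

    dna: np.ndarray
    reporter: np.ndarray
    truth: pd.DataFrame
    cells: list[GroundTruthCell] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.shape


def _nucleus_mask_coords(cell: GroundTruthCell, shape: tuple[int, int]):
    from skimage.draw import ellipse

    return ellipse(
        cell.nucleus_center[0],
        cell.nucleus_center[1],
        cell.nucleus_axes[0],
        cell.nucleus_axes[1],
        shape=shape,
        rotation=cell.nucleus_angle,
    )


def _add_gaussian_spot(img: np.ndarray, r: float, c: float, intensity: float, sigma: float):
    h, w = img.shape
    half = int(math.ceil(4.0 * sigma))
    r0, r1 = int(math.floor(r)) - half, int(math.floor(r)) + half + 1
    c0, c1 = int(math.floor(c)) - half, int(math.floor(c)) + half + 1
    rr = np.arange(max(r0, 0), min(r1, h))
    cc = np.arange(max(c0, 0), min(c1, w))
    if rr.size == 0 or cc.size == 0:
        return
    kern = np.exp(
        -(((rr[:, None] - r) ** 2) + ((cc[None, :] - c) ** 2)) / (2.0 * sigma * sigma)
    )
    total = kern.sum()
    if total > 0:
        img[np.ix_(rr, cc)] += intensity * kern / total


def render_scene(cells: Sequence[GroundTruthCell], spec: SceneSpec) -> RenderedField:
    """Render a two-channel field from ground-truth cells.

    The DNA channel places a flat elliptical profile per nucleus whose
    integrated (background-subtracted) signal equals the cell's
    ``dna_content`` exactly; the reporter channel places unit-mass Gaussian
    kernels scaled by each spot intensity, so noise-free reporter signal
    above background conserves the planted intensity mass.  Noise, if any,
    is applied last.  Bit-identical for identical inputs.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    if h <= 0 or w <= 0:
        raise ValueError("image dimensions must be positive")
    dna = np.full((h, w), float(spec.background_dna))
    rfp = np.full((h, w), float(spec.background_rfp))
    for cell in cells:
        rr, cc = _nucleus_mask_coords(cell, (h, w))
        if rr.size == 0:
            continue
        dna[rr, cc] += cell.dna_content / rr.size
        for (sr, sc), inten in zip(cell.spot_positions, cell.spot_intensities):
            _add_gaussian_spot(rfp, sr, sc, inten, spec.spot_sigma_px)
    if spec.noise_model == "poisson_gaussian":
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
        dna = rng.poisson(np.clip(dna, 0, None)).astype(float)
        rfp = rng.poisson(np.clip(rfp, 0, None)).astype(float)
        if spec.read_sigma > 0:
            dna += rng.normal(0.0, spec.read_sigma, size=dna.shape)
            rfp += rng.normal(0.0, spec.read_sigma, size=rfp.shape)
        np.clip(dna, 0.0, None, out=dna)
        np.clip(rfp, 0.0, None, out=rfp)
    return RenderedField(dna=dna, reporter=rfp, truth=ground_truth_table(cells), cells=list(cells))


def render_field(spec: SceneSpec) -> RenderedField:
    """Sample a population and render it in one step."""
    return render_scene(sample_cell_population(spec), spec)


# ---------------------------------------------------------------------------
# plate screens
# ---------------------------------------------------------------------------


CONTROL_ID = "control"


@dataclass
class ScreenDataset:
    """A simulated plate screen: plate map, truth labels, and data.

    ``cells`` holds the per-cell table for table fidelity; ``images`` maps
    well id to its rendered fields for image fidelity.
    """

    plate_map: pd.DataFrame  # well_id, compound_id, replicate, role
    truth: pd.DataFrame  # compound_id, archetype
    fidelity: str
    cells: pd.DataFrame | None = None
    images: dict[str, list[RenderedField]] | None = None


def _apply_effect(spec: SceneSpec, effect: CompoundEffect | None) -> SceneSpec:
    if effect is None:
        return spec
    changes: dict = {}
    if effect.phase_shift is not None:
        changes["phase_fractions"] = tuple(effect.phase_shift)
    if effect.perox_multiplier != 1.0:
        changes["spot_rate_per_phase"] = tuple(
            r * effect.perox_multiplier for r in spec.spot_rate_per_phase
        )
    return replace(spec, **changes) if changes else spec


def _sample_well_table(
    spec: SceneSpec,
    n_cells: int,
    rng: np.random.Generator,
    n_fields: int,
) -> pd.DataFrame:
    """Fast vectorized per-cell table straight from the generative model."""
    p = np.asarray(spec.phase_fractions, dtype=float)
    phases = rng.choice(3, size=n_cells, p=p)
    dna = _sample_dna_content(rng, phases, spec.dna_2n_mean, spec.dna_cv)
    rates = np.asarray(spec.spot_rate_per_phase, dtype=float)[phases]
    counts = rng.poisson(rates)
    # gamma(shape=k, scale=m) is the sum of k exponential spot intensities
    totals = rng.gamma(np.maximum(counts, 1e-12), spec.spot_intensity_mean)
    totals[counts == 0] = 0.0
    return pd.DataFrame(
        {
            "field_index": rng.integers(0, n_fields, size=n_cells),
            "cell_label": np.arange(1, n_cells + 1),
            "integrated_dna": dna,
            "spot_count": counts,
            "spot_total_intensity": totals,
            "phase_true": np.asarray(PHASES)[phases],
        }
    )


def simulate_screen(
    n_compounds: int,
    effects: Sequence[CompoundEffect],
    n_replicates: int = 3,
    fidelity: str = "table",
    base_spec: SceneSpec | None = None,
    seed: int = 0,
    n_fields: int = 12,
    cells_per_well: int = 2000,
) -> ScreenDataset:
    """Simulate a multi-replicate compound screen with truth labels.

    Table fidelity emits per-cell tables directly from the generative model
    (the fast path for library-scale screens); image fidelity renders
    ``n_fields`` two-channel fields per well.  A control well (no effect) is
    included on every replicate.  Well cell counts are Poisson around
    ``cells_per_well`` scaled by any cytotoxic survival fraction.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(effects) != n_compounds:
        raise ValueError("need exactly one effect per compound")
    ids = [e.compound_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound_id in effects")
    if fidelity not in ("table", "image"):
        raise ValueError(f"unknown fidelity {fidelity!r}")
    for e in effects:
        e.validate()
    if base_spec is None:
        base_spec = SceneSpec()
    base_spec.validate()

    ss = np.random.SeedSequence((seed, 2))
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append((CONTROL_ID, rep, "control", None))
        for e in effects:
            rows.append((e.compound_id, rep, "compound", e))

    plate_rows = []
    cell_frames = []
    images: dict[str, list[RenderedField]] = {}
    child_seeds = ss.spawn(len(rows))
    for idx, ((cid, rep, role, eff), child) in enumerate(zip(rows, child_seeds)):
        well_id = f"r{rep:02d}w{idx % (n_compounds + 1):04d}"
        plate_rows.append(
            {"well_id": well_id, "compound_id": cid, "replicate": rep, "role": role}
        )
        spec = _apply_effect(base_spec, eff)
        survival = 1.0 if eff is None else eff.survival_fraction
        rng = np.random.default_rng(child)
        if fidelity == "table":
            n = int(rng.poisson(cells_per_well * survival))
            tab = _sample_well_table(spec, n, rng, n_fields)
            tab.insert(0, "well_id", well_id)
            cell_frames.append(tab)
        else:
            per_field = max(int(round(cells_per_well * survival / n_fields)), 0)
            fields = []
            for f_idx in range(n_fields):
                fspec = replace(
                    spec,
                    n_cells=int(rng.poisson(per_field)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                fields.append(render_field(fspec))
            images[well_id] = fields

    truth = pd.DataFrame(
        {"compound_id": ids, "archetype": [e.archetype for e in effects]}
    )
    return ScreenDataset(
        plate_map=pd.DataFrame(plate_rows),
        truth=truth,
        fidelity=fidelity,
        cells=pd.concat(cell_frames, ignore_index=True) if cell_frames else None,
        images=images or None,
    )


# ---------------------------------------------------------------------------
# flow cytometry events
# ---------------------------------------------------------------------------


def simulate_flow_events(spec: FlowConditionSpec) -> pd.DataFrame:
    """Simulate a per-event flow table (columns: dna, peroxisome, dcfda, pi).

    PI is a two-component lognormal mixture weighted by ``dead_fraction``;
    DCFDA is lognormal with its mean scaled by ``ros_fold``; DNA and
    peroxisome follow the same phase-linked model as the imaging generator.
    ``is_dead_true`` records the planted mixture component.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 3)))
    n = spec.n_events
    dead = rng.random(n) < spec.dead_fraction
    pi = np.where(
        dead,
        _lognormal(rng, spec.pi_dead_mean, spec.pi_cv, n),
        _lognormal(rng, spec.pi_live_mean, spec.pi_cv, n),
    )
    dcfda = _lognormal(rng, spec.dcfda_mean * spec.ros_fold, spec.dcfda_cv, n)
    phases = rng.choice(3, size=n, p=np.asarray(spec.phase_fractions, dtype=float))
    dna = _sample_dna_content(rng, phases, spec.dna_2n_mean, spec.dna_cv)
    rates = np.asarray(spec.perox_rate_per_phase, dtype=float)[phases]
    counts = rng.poisson(rates)
    perox = rng.gamma(np.maximum(counts, 1e-12), spec.spot_intensity_mean)
    perox[counts == 0] = 0.0
    return pd.DataFrame(
        {
            "condition_id": spec.condition_id,
            "dna": dna,
            "peroxisome": perox,
            "dcfda": dcfda,
            "pi": pi,
            "phase_true": np.asarray(PHASES)[phases],
            "is_dead_true": dead,
        }
    )
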
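"""Nuclear segmentation and simulated-cytoplasm compartmentalization.

Nuclei are detected as primary objects on the DNA channel; clustered and
border-touching objects are flagged for exclusion rather than split; each
retained nucleus receives a neighbor-constrained cytoplasmic zone built by
a seeded nearest-nucleus distance partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs for nucleus detection and exclusion."""

    smooth_sigma: float = 2.0
    min_area: int = 20
    max_area: int | None = None
    cluster_max_area_factor: float = 1.6  # times the field median nuclear area
    cluster_min_solidity: float = 0.85
    cytoplasm_extent_px: float = 15.0
    block_flagged: bool = False  # flagged nuclei block instead of freeing territory


@dataclass
class NucleusObject:
    """One detected nucleus (primary object)."""

    label: int
    centroid: tuple[float, float]
    area: int
    integrated_dna: float
    background: float = 0.0  # per-field background level used for integration
    edge_flag: bool = False
    cluster_flag: bool = False

    @property
    def excluded(self) -> bool:
        return self.edge_flag or self.cluster_flag


@dataclass
class CompartmentMap:
    """Per-cell nucleus and cytoplasm label images for one field.

    Cytoplasm regions share the label of their owning nucleus; label 0 is
    background.  Nucleus and cytoplasm of a cell are disjoint, cytoplasm
    regions of different cells are disjoint, and every cytoplasm pixel lies
    within the configured extent of its own nucleus and is closer to it than
    to any other retained nucleus.
    """

    nucleus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    well_id: str = ""
    field_index: int = 0

    def cytoplasm_mask(self, lab: int) -> np.ndarray:
        return self.cytoplasm_labels == lab


def detect_nuclei(
    dna_channel: np.ndarray, params: SegmentationParams | None = None
) -> tuple[list[NucleusObject], np.ndarray]:
    """Detect nuclei on the DNA channel.

    Thresholds a Gaussian-smoothed image with a global Otsu threshold, fills
    holes, labels connected components and size-filters them.  The per-field
    background estimate is the median of sub-threshold raw pixels;
    ``integrated_dna`` is the sum of (pixel - background) over each mask.

    Returns the nucleus objects and the nucleus label image (0=background).
    A constant image yields zero nuclei; negative pixels raise.
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(dna_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("dna_channel must be 2-D")
    if np.any(img < 0):
        raise ValueError("dna_channel must be non-negative")
    empty = np.zeros(img.shape, dtype=np.int32)
    if img.max() == img.min():
        return [], empty

    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    # Otsu on log intensities: robust to the wide dynamic range between the
    # dim (2N) and bright (4N) nucleus classes, which skews plain Otsu high
    thr = float(np.expm1(threshold_otsu(np.log1p(smoothed))))
    mask = smoothed > thr
    mask = ndi.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)

    below = img[~mask]
    background = float(np.median(below)) if below.size else 0.0

    nuclei: list[NucleusObject] = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_label = 1
    for prop in regionprops(labels, intensity_image=img):
        if prop.area < params.min_area:
            continue
        if params.max_area is not None and prop.area > params.max_area:
            continue
        integrated = float(prop.image_intensity[prop.image].sum() - background * prop.area)
        nuclei.append(
            NucleusObject(
                label=next_label,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=int(prop.area),
                integrated_dna=max(integrated, 0.0),
                background=background,
            )
        )
        keep[prop.label] = next_label
        next_label += 1
    relabeled = keep[labels]
    return nuclei, relabeled


def flag_excluded_nuclei(
    nuclei: Sequence[NucleusObject],
    label_image: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[NucleusObject]:
    """Set edge/cluster exclusion flags in place and return the list.

    ``edge_flag``: the mask touches any image border.  ``cluster_flag``: the
    object's area exceeds ``cluster_max_area_factor`` times the field median
    nuclear area, or its solidity falls below ``cluster_min_solidity`` —
    both signatures of merged nuclei.
    """
    if params is None:
        params = SegmentationParams()
    if not nuclei:
        return list(nuclei)
    border = np.concatenate(
        [label_image[0, :], label_image[-1, :], label_image[:, 0], label_image[:, -1]]
    )
    border_labels = set(np.unique(border[border > 0]).tolist())
    median_area = float(np.median([n.area for n in nuclei]))
    solidity = {}
    for prop in regionprops(label_image):
        solidity[prop.label] = float(prop.solidity)
    for n in nuclei:
        n.edge_flag = n.label in border_labels
        too_big = n.area > params.cluster_max_area_factor * median_area
        too_concave = solidity.get(n.label, 1.0) < params.cluster_min_solidity
        n.cluster_flag = bool(too_big or too_concave)
    return list(nuclei)


def build_cytoplasm_regions(
    nucleus_label_image: np.ndarray,
    retained_labels: Iterable[int],
    max_extent_px: float,
    blocked_labels: Iterable[int] = (),
    well_id: str = "",
    field_index: int = 0,
) -> CompartmentMap:
    """Build the simulated cytoplasm by a seeded distance partition.

    Each cytoplasm region consists of the non-nuclear pixels within
    ``max_extent_px`` of its nucleus that are closer to that nucleus than to
    any other retained nucleus.  ``blocked_labels`` (optional) makes flagged
    nuclei block territory instead of freeing it.
    """
    if max_extent_px <= 0:
        raise ValueError("max_extent_px must be positive")
    retained = sorted(set(int(l) for l in retained_labels))
    if not retained:
        raise ValueError("retained_labels must be non-empty")
    labels = np.asarray(nucleus_label_image)
    retained_img = np.where(np.isin(labels, retained), labels, 0).astype(np.int32)
    seeds = retained_img > 0
    if not seeds.any():
        raise ValueError("no retained nucleus pixels in the label image")
    dist, (ir, ic) = ndi.distance_transform_edt(~seeds, return_indices=True)
    owner = retained_img[ir, ic]
    cyto = np.where((dist > 0) & (dist <= max_extent_px), owner, 0).astype(np.int32)
    cyto[labels > 0] = 0  # nuclear pixels (retained or not) are never cytoplasm
    blocked = set(int(l) for l in blocked_labels)
    if blocked:
        block_mask = np.isin(labels, sorted(blocked))
        bdist = ndi.distance_transform_edt(~block_mask)
        cyto[bdist < dist] = 0
    return CompartmentMap(
        nucleus_labels=retained_img,
        cytoplasm_labels=cyto,
        well_id=well_id,
        field_index=field_index,
    )


def segment_field(
    dna_channel: np.ndarray,
    params: SegmentationParams | None = None,
    well_id: str = "",
    field_index: int = 0,
) -> tuple[list[NucleusObject], np.ndarray, CompartmentMap | None]:
    """Detect, flag, and compartmentalize in one call.

    Returns (all nuclei with flags, nucleus label image, compartment map of
    the retained nuclei — or None if every nucleus was excluded).
    """
    if params is None:
        params = SegmentationParams()
    nuclei, labels = detect_nuclei(dna_channel, params)
    flag_excluded_nuclei(nuclei, labels, params)
    retained = [n.label for n in nuclei if not n.excluded]
    if not retained:
        return nuclei, labels, None
    flagged = [n.label for n in nuclei if n.excluded]
    comp = build_cytoplasm_regions(
        labels,
        retained,
        params.cytoplasm_extent_px,
        blocked_labels=flagged if params.block_flagged else (),
        well_id=well_id,
        field_index=field_index,
    )
    return nuclei, labels, comp


def nuclei_table(
    nuclei: Sequence[NucleusObject], well_id: str = "", field_index: int = 0
) -> pd.DataFrame:
    """Per-nucleus table matching the CSV export schema."""
    return pd.DataFrame(
        {
            "well": well_id,
            "field": field_index,
            "label": [n.label for n in nuclei],
            "centroid_row": [n.centroid[0] for n in nuclei],
            "centroid_col": [n.centroid[1] for n in nuclei],
            "area": [n.area for n in nuclei],
            "integrated_dna": [n.integrated_dna for n in nuclei],
            "edge_flag": [n.edge_flag for n in nuclei],
            "cluster_flag": [n.cluster_flag for n in nuclei],
        }
    )
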
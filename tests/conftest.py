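import numpy as np
import pytest

from peroxiscreen.segmentation import SegmentationParams, segment_field
from peroxiscreen.synthetic import SceneSpec, render_scene, sample_cell_population


@pytest.fixture(scope="session")
def sparse_spec():
    """Low-density noise-free scene where detection is essentially perfect."""
    return SceneSpec(seed=11, n_cells=15, spot_rate_per_phase=(4.0, 6.0, 7.0))


@pytest.fixture(scope="session")
def sparse_scene(sparse_spec):
    cells = sample_cell_population(sparse_spec)
    return cells, render_scene(cells, sparse_spec)


@pytest.fixture(scope="session")
def sparse_segmented(sparse_scene):
    cells, fld = sparse_scene
    nuclei, labels, comp = segment_field(fld.dna)
    return cells, fld, nuclei, labels, comp


@pytest.fixture(scope="session")
def mixed_spec():
    """Field with planted edge and clustered nuclei."""
    return SceneSpec(seed=4, n_cells=50, edge_fraction=0.1, cluster_fraction=0.1)


@pytest.fixture(scope="session")
def mixed_scene(mixed_spec):
    cells = sample_cell_population(mixed_spec)
    return cells, render_scene(cells, mixed_spec)


def match_to_truth(kept_nuclei, cells):
    """Map detected nuclei to ground-truth cells by nearest centroid."""
    from scipy.spatial.distance import cdist

    kc = np.array([n.centroid for n in kept_nuclei])
    tc = np.array([c.nucleus_center for c in cells])
    d = cdist(kc, tc)
    idx = d.argmin(axis=1)
    return idx, d.min(axis=1)
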
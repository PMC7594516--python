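import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sodakit import synthetic
from sodakit.segmentation import ForegroundMask

PIXEL_SIZE = 15.0


@pytest.fixture(scope="session")
def dendrite_mask():
    return synthetic.generate_roi_mask((512, 512), "dendrite_band", seed=1)


@pytest.fixture(scope="session")
def full_mask():
    return synthetic.generate_roi_mask((512, 512), "full", seed=1)


@pytest.fixture(scope="session")
def csr_truth():
    """Two independent CSR channels (f = 0) on a dendrite band."""
    cfg = synthetic.SimulationConfig(
        n_clusters_ch1=400, n_clusters_ch2=400, coupling_fraction=0.0, seed=3
    )
    return synthetic.simulate_cluster_pairs(cfg)


@pytest.fixture(scope="session")
def coupled_truth():
    """Half the channel-1 clusters have a partner at 40 +/- 2 nm."""
    cfg = synthetic.SimulationConfig(
        n_clusters_ch1=500, n_clusters_ch2=500, coupling_fraction=0.5,
        coupling_distance_mean=40.0, coupling_distance_sd=2.0, seed=4,
    )
    return synthetic.simulate_cluster_pairs(cfg)


@pytest.fixture(scope="session")
def rendered_field():
    """A moderately sparse rendered field with ground truth."""
    cfg = synthetic.SimulationConfig(
        image_shape=(1024, 1024), n_clusters_ch1=200, n_clusters_ch2=0,
        roi_style="full", seed=3,
    )
    truth = synthetic.simulate_cluster_pairs(cfg)
    ch1, ch2 = synthetic.render_image_pair(truth, cfg)
    return cfg, truth, ch1


def as_fg(mask_array, pixel_size=PIXEL_SIZE):
    return ForegroundMask(mask_array, pixel_size)
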
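import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from deltarad.preprocessing import preprocess
from deltarad.synthetic import CohortConfig, generate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_patients=4, seed=7)


@pytest.fixture(scope="session")
def patient(small_config):
    return generate_patient(small_config, 0)


@pytest.fixture(scope="session")
def preprocessed(patient):
    """Both timepoints of one synthetic patient through the full pipeline."""
    return {
        "before": preprocess(patient.before, patient.rois_before.tumor, patient.rois_before.bladder),
        "after": preprocess(patient.after, patient.rois_after.tumor, patient.rois_after.bladder),
    }


def random_quantized_roi(rng, shape=(5, 5, 5), n_levels=6, p_mask=0.7):
    """Small random ROI for oracle-equivalence checks; returns
    (levels, mask, n_levels) with at least 2 in-mask voxels."""
    while True:
        mask = rng.random(shape) < p_mask
        if mask.sum() >= 2:
            break
    levels = rng.integers(1, n_levels + 1, size=shape)
    levels = np.where(mask, levels, 0)
    return levels, mask, n_levels
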
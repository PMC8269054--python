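import warnings

import numpy as np
import pytest
from hypothesis import settings

from msirisk import preprocess, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_study():
    """Small noiseless two-group study: datasets, truth, and the tumor peak matrix."""
    cfg = synth.SynthConfig(seed=1, noise_sd=0.0, tic_variation=None)
    datasets, truth = synth.generate_msi_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = [preprocess.tic_normalize(d) for d in datasets]
        centers = preprocess.find_peaks(norm)
        intervals = preprocess.align_peaks(centers)
        rois = [truth.roi_for(d.sample_id) for d in datasets]
        pm = preprocess.build_peak_matrix(norm, intervals, rois)
    return {"config": cfg, "datasets": datasets, "truth": truth, "pm": pm}


@pytest.fixture(scope="session")
def tumor_matrix(clean_study):
    pm = clean_study["pm"]
    return pm.subset(pm.roi_mask(synth.TUMOR_LABEL))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
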
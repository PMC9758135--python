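import numpy as np
import pytest

import preptemplate as pt
from preptemplate.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """One-subject noiseless configuration used by recovery tests."""
    return PipelineConfig(
        cohort=pt.CohortSpec(n_subjects=1, n_voxels=30, seed=5,
                             behavioral_accuracy=1.0),
        overlap=0.0, noise_sd=0.0, n_perm=5)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_cfg):
    return pt.generate_cohort(noiseless_cfg.cohort, noiseless_cfg.overlap,
                              **noiseless_cfg.truth_kwargs())[0]


@pytest.fixture(scope="session")
def noiseless_patterns(noiseless_subject, noiseless_cfg):
    from preptemplate.pipeline import subject_patterns
    return subject_patterns(noiseless_subject, noiseless_cfg)
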
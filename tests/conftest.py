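import pytest

from capdyn.io import concatenate_cohort, normalize_subject
from capdyn.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Small two-group cohort: 8+8 subjects, 40 ROIs, 120 frames, K=4."""
    return SyntheticConfig(
        k_states=4, n_rois=40, n_subjects_per_group=8,
        frames_per_subject=120, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    bundle, _ = small_cohort
    return concatenate_cohort([normalize_subject(ts) for ts in bundle.subjects])
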
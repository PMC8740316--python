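import numpy as np
import pytest

from perafkit import Bold4D, EffectSpec, PhenotypeModel, SyntheticCohortConfig, cube_roi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast cohort: 3 per group, 16x16x12 grid, 60 volumes, one planted ROI."""
    return SyntheticCohortConfig(
        n_per_group=3,
        grid_shape=(16, 16, 12),
        n_timepoints=60,
        effects=(
            EffectSpec(roi_id=1, roi_voxels=cube_roi((6, 6, 4), 3),
                       amplitude_multiplier=1.5),
        ),
        phenotype_models=(
            PhenotypeModel(name="anxiety_score", linked_roi_id=1, target_r=-0.8,
                           mean=8.0, sd=2.0),
        ),
        seed=7,
    )


@pytest.fixture
def random_bold(rng):
    """A positive-baseline random 4D volume, 3 mm voxels."""
    data = rng.normal(1000.0, 20.0, size=(6, 5, 4, 40))
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    return Bold4D(data=data, affine=aff, tr_seconds=2.0)
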
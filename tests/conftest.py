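import numpy as np
import pytest

from netcog.synthetic_cohort import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A fast cohort configuration for pipeline-level tests."""
    defaults = dict(n_patients=20, n_controls=12, n_rois=30, n_timepoints=80,
                    module_size=10, seed=0)
    defaults.update(overrides)
    return CohortConfig(**defaults)


#: coarse sparsity grid for fast tests (same range, wider step)
COARSE_GRID = np.arange(10, 41, 5) / 100.0


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort shared across pipeline tests."""
    return generate_cohort(small_config(seed=7), grid=COARSE_GRID)
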
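import numpy as np
import pytest

from netpsych.synthetic_cohort import BoldRun, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects (2 per group), short runs; shared across modules."""
    config = default_config(7, n_per_group=2, n_volumes=60)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (11+11 subjects); generated once."""
    config = default_config(0)
    return config, generate_cohort(config)


def make_bold(series: np.ndarray, spacing_mm: float = 10.0, tr: float = 2.0) -> BoldRun:
    """Wrap a V x T array as a single-row BoldRun (voxels along x)."""
    v, t = series.shape
    data = series.reshape(v, 1, 1, t).astype(float)
    mask = np.ones((v, 1, 1), dtype=bool)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[0, 3] = -spacing_mm * (v - 1) / 2.0
    return BoldRun(data=data, mask=mask, affine=affine, tr=tr)
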
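import numpy as np
import pytest

from qoctga.synthetic_cohort import CohortConfig, TruncatedNormal, simulate_cohort


def small_config(**overrides) -> CohortConfig:
    """A coarse, fast cohort configuration for unit tests."""
    defaults = dict(
        n_per_arm={"SHAM": 1},
        grid_px=(150, 150),
        n_bscans=25,
        rng_seed=42,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One rendered sham eye at coarse resolution, with ground truth."""
    groups, truth = simulate_cohort(small_config())
    return groups, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Rendered cohort with exact feature relations: no HTR noise, halo > 0."""
    cfg = small_config(
        n_per_arm={"SHAM": 2, "PM": 1},
        htr_agreement=1.0,
        fovea_jitter_mm=0.0,
        rng_seed=5,
    )
    groups, truth = simulate_cohort(cfg)
    return cfg, groups, truth


def disc_mask(shape, center, radius_px) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
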
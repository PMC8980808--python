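import dataclasses

import pytest

from radimm.cohort import SyntheticConfig, generate_cohort

# Reduced grid for unit tests: all four shells present but cheap to render.
SMALL_KW = dict(
    grid_shape=(24, 24, 24),
    voxel_size_mm=(4.0, 4.0, 4.0),
    roi_radii_mm=(8.0, 16.0, 22.0, 30.0),
    icv_radius_mm=44.0,
)


def small_config(**overrides) -> SyntheticConfig:
    kw = {**SMALL_KW, **overrides}
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    """16 subjects, every site sampled, reduced grid."""
    cfg = small_config(
        n_subjects=16,
        seed=11,
        missing_site_prob={"necrosis": 0.0, "core": 0.0, "margin": 0.0},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_study(small_cohort):
    return small_cohort.studies[0]


def replace_config(cfg: SyntheticConfig, **kw) -> SyntheticConfig:
    return dataclasses.replace(cfg, **kw)
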
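import pytest
from hypothesis import settings

from brainlipidome.preprocess import IntensityMatrix, normalize_intensities

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from brainlipidome.synthetic import SyntheticConfig, generate_atlas

# reduced atlas for unit tests: same structure, smaller everything
SMALL_KW = dict(
    n_regions=30,
    n_individuals=4,
    n_cortical=20,
    n_fc_regions=16,
    n_expr_regions=15,
    category_counts={"myelin_pos": 30, "myelin_neg": 12, "unexplained": 12,
                     "housekeeping": 12, "variable": 4},
    n_hierarchy_lipids=4,
    seed=11,
)


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas(SyntheticConfig(**SMALL_KW))


@pytest.fixture(scope="session")
def small_normalized(small_atlas):
    mat = normalize_intensities(
        IntensityMatrix(small_atlas.intensity),
        small_atlas.sample_meta,
        small_atlas.standards_medians,
    )
    return mat.data
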
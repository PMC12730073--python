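import numpy as np
import pytest

from radrobust.io import AlignedPair, FeatureTable, align_platforms
from radrobust.synthetic import SimulationConfig, generate_platform_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    values = np.array([
        [1.0, 10.0, 0.5, 3.0],
        [2.0, 20.0, 0.2, 1.0],
        [3.0, 30.0, 0.9, 2.0],
    ])
    return FeatureTable(
        "A",
        ["L1", "L2", "L3"],
        [
            "original_firstorder_mean",
            "original_glcm_contrast",
            "wavelet_hlh_glcm_clustershade",
            "original_shape_sphericity",
        ],
        values,
    )


@pytest.fixture
def copy_pair():
    """Aligned pair where platform B is an exact copy of A."""
    cfg = SimulationConfig(n_lesions=60, n_features=24, n_blocks=3, seed=11)
    a, _, _ = generate_platform_pair(cfg)
    b = FeatureTable("B", list(a.lesion_ids), list(a.feature_names),
                     a.values.copy())
    return align_platforms(a, b)


@pytest.fixture
def synthetic_pair():
    cfg = SimulationConfig(n_lesions=100, n_features=36, n_blocks=4,
                           noise_sd=0.05, seed=5)
    a, b, truth = generate_platform_pair(cfg)
    return align_platforms(a, b), truth


def make_block_distance(sizes, within=0.1, between=2.0):
    """Distance matrix with perfectly separated blocks."""
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture
def aligned_pair_factory():
    def make(seed=0, **kwargs) -> tuple[AlignedPair, object]:
        cfg = SimulationConfig(seed=seed, **kwargs)
        a, b, truth = generate_platform_pair(cfg)
        return align_platforms(a, b), truth

    return make
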
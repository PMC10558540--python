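import numpy as np
import pytest

from craniomap import LandmarkConfiguration, SpecimenSet, SyntheticSpec, simulate
from craniomap.synthetic import make_base_shape


@pytest.fixture(scope="session")
def base60():
    """Small symmetric ellipsoid base shape with its triangulation."""
    return make_base_shape(60, seed=0)


@pytest.fixture(scope="session")
def null_small():
    """Small exchangeable-groups sample: no planted effect, identical sizes."""
    spec = SyntheticSpec(
        n_points=60, n_per_group=(16, 16), size_means=(780.0, 780.0),
        size_sds=(25.0, 25.0), noise_sd=0.3, seed=5,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def dimorphic_small():
    """Small sample with a planted localized shape effect and size dimorphism."""
    base, _ = make_base_shape(60, seed=0)
    from craniomap.synthetic import mean_nearest_neighbor_distance, patch_indices

    patch = patch_indices(base, 5, 8)
    spacing = mean_nearest_neighbor_distance(base.coords)
    spec = SyntheticSpec(
        n_points=60, n_per_group=(16, 16),
        effect_indices=tuple(int(i) for i in patch),
        effect_size=6 * 0.3 / spacing,
        noise_sd=0.3, seed=5,
    )
    specimens, truth = simulate(spec)
    truth["patch"] = patch
    return specimens, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_simple_config(coords, pairs=(), midline=()):
    coords = np.asarray(coords, dtype=float)
    return LandmarkConfiguration(
        point_ids=tuple(f"p{i}" for i in range(len(coords))),
        coords=coords,
        pairs=pairs,
        midline=midline,
    )


def make_specimen_set(stack, sex=None, ids=None):
    stack = np.asarray(stack, dtype=float)
    s, n = stack.shape[0], stack.shape[1]
    return SpecimenSet(
        coords=stack,
        specimen_ids=tuple(ids) if ids is not None else tuple(f"s{i}" for i in range(s)),
        sex=tuple(sex) if sex is not None else (None,) * s,
        point_ids=tuple(f"p{j}" for j in range(n)),
    )
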
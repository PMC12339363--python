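import numpy as np
import pytest

from vatmap.spatial_io import DensityVolume, GridSpec, Tractogram


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def make_random_tractogram(rng, n_streamlines=8, n_points=(4, 12), scale=20.0):
    """Random polylines with contiguous small steps inside [-scale, scale]^3."""
    sls = []
    for _ in range(n_streamlines):
        n = int(rng.integers(n_points[0], n_points[1] + 1))
        start = rng.uniform(-scale, scale, 3)
        steps = rng.normal(0.0, 1.5, (n - 1, 3))
        sls.append(np.vstack([start, start + np.cumsum(steps, axis=0)]))
    return Tractogram(sls, space_tag="synthetic")


def make_random_volume(rng, dims=(9, 9, 9), voxel_size=1.0, origin=(-4.0, -4.0, -4.0)):
    grid = GridSpec(origin=origin, voxel_size=voxel_size, dims=dims)
    return DensityVolume(grid, rng.random(dims))


@pytest.fixture
def random_tractogram(rng):
    return make_random_tractogram(rng)


@pytest.fixture
def random_volume(rng):
    return make_random_volume(rng)
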
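import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from synaptomap import synthgen
from synaptomap.volcore import Volume, VoxelGrid


@pytest.fixture
def unit_grid():
    """64-cube grid with unit voxels, for geometry-free tests."""
    return VoxelGrid((64, 64, 64), (1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


def make_volume(data, role="molecular", voxel_size_nm=(1.0, 1.0, 1.0)):
    data = np.asarray(data)
    return Volume(VoxelGrid(data.shape, voxel_size_nm), data, role=role)


def add_blob(arr, centre, sigma, peak):
    """Gaussian blob helper for hand-built fixtures (sigma scalar or triple)."""
    sigma = np.broadcast_to(np.asarray(sigma, float), (3,))
    lo = [max(int(c - 4 * s), 0) for c, s in zip(centre, sigma)]
    hi = [min(int(c + 4 * s) + 1, n) for c, s, n in zip(centre, sigma, arr.shape)]
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = sum(
        (ax - c) ** 2 / (2 * s**2)
        for ax, c, s in zip((zz, yy, xx), centre, sigma)
    )
    arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * np.exp(-q)


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free scene at paper-like density, shared across tests."""
    grid = synthgen.make_grid(2.5)
    params = synthgen.SceneParams(grid=grid, seed=424242, exact_count=15)
    return synthgen.generate_scene(params)
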
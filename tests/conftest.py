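"""Shared fixtures: synthetic NIfTI fixtures are generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from voxelgraph.synthetic import (
    CommunitySpec,
    block_communities,
    generate_bold,
    generate_index_image,
)


@pytest.fixture(scope="session")
def index_image(tmp_path_factory):
    """4x4x4x10 test-pattern image (intensity = linear_index*1000 + t) + full mask."""
    out = tmp_path_factory.mktemp("index_image")
    image_path, mask_path = generate_index_image((4, 4, 4), 10, out)
    return image_path, mask_path


@pytest.fixture(scope="session")
def community_dataset(tmp_path_factory):
    """Planted-community BOLD fixture: 5 communities x 50 voxels, rho_within = 0.9."""
    out = tmp_path_factory.mktemp("community")
    spec = CommunitySpec(
        grid_dims=(10, 5, 5),
        n_volumes=400,
        communities=block_communities((10, 5, 5), 5, 50, amplitude=3.0),
        noise_sd=1.0,
        seed=7,
    )
    image_path, mask_path, truth = generate_bold(spec, out)
    return spec, image_path, mask_path, truth


def random_table(rng: np.random.Generator, n_timepoints: int, n_voxels: int):
    """A VoxelTable of i.i.d. noise on a 1-voxel-deep grid, for unit tests."""
    from voxelgraph.nifti_io import VoxelTable

    return VoxelTable(
        data=rng.standard_normal((n_timepoints, n_voxels)),
        index_map=np.arange(n_voxels),
        grid_dims=(n_voxels, 1, 1),
        affine=np.eye(4),
    )
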
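"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cardiocap3d import synth
from cardiocap3d.grid import VoxelGrid


@pytest.fixture(autouse=True)
def _quiet_raster_warnings():
    # the thin-tube raster warning is a documented contract, exercised
    # explicitly where it matters; keep the rest of the suite quiet
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*exceeds the smallest tube radius.*"
        )
        warnings.filterwarnings("ignore", message="packing stalled.*")
        yield


def tube_mask(paths, radius, shape=(40, 60, 60), voxel_size=(1.0, 1.0, 1.0)):
    """Rasterise explicit polyline tubes into a boolean VoxelGrid."""
    segs = [
        synth.VesselSegmentTruth(i, np.asarray(p, dtype=float), radius)
        for i, p in enumerate(paths)
    ]
    out = np.zeros(shape, dtype=bool)
    synth._paint_tubes(out, segs, np.asarray(voxel_size, dtype=float))
    return VoxelGrid(out, voxel_size)


@pytest.fixture(scope="session")
def small_tree():
    """A well-separated straight-tube network with exact ground truth."""
    return synth.generate_well_separated_tree(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy rendered dataset (tree + sleeves + all six channels)."""
    rng = np.random.default_rng(11)
    s1, s2, s3 = (int(v) for v in rng.integers(0, 2**31 - 1, size=3))
    tree = synth.generate_vascular_tree((35.0, 120.0, 120.0), 120, seed=s1)
    tree = synth.plant_empty_sleeves(tree, 0.05, seed=s2)
    return synth.rasterize(tree, noise_sd=200.0, seed=s3)
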
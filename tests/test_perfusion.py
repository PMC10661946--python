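"""Perfusion, dextran leak, hypoxia, diffusion distance and PAS formulas."""

import numpy as np
import pytest

from cardiocap3d import synth
from cardiocap3d.grid import VoxelGrid
from cardiocap3d.perfusion import (
    diffusion_distance_stats,
    extravascular_dextran_percentage,
    hypoxia_stats,
    pas_area_percentage,
    perfusion_percentage,
)
from cardiocap3d.pruning import STRUCTURAL_SEG_PARAMS
from cardiocap3d.segmentation import multiscale_multilevel_segment


def mask(values, vs=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(values, dtype=bool), vs)


class TestPerfusionPercentage:
    def test_full_partial_empty(self):
        icam2 = np.zeros((4, 8, 8), dtype=bool)
        icam2[:, :4] = True
        full = perfusion_percentage(mask(icam2), mask(icam2))
        half_ib4 = icam2.copy()
        half_ib4[:, :2] = icam2[:, :2]
        half_ib4[:, 2:4] = False
        half = perfusion_percentage(mask(half_ib4), mask(icam2))
        empty = perfusion_percentage(mask(np.zeros_like(icam2)), mask(icam2))
        assert (full, half, empty) == (100.0, 50.0, 0.0)

    def test_voxels_outside_icam2_ignored_unless_raw(self):
        icam2 = np.zeros((4, 8, 8), dtype=bool)
        icam2[:, :4] = True
        ib4 = np.ones_like(icam2)  # spills everywhere
        assert perfusion_percentage(mask(ib4), mask(icam2)) == 100.0
        assert perfusion_percentage(mask(ib4), mask(icam2), raw_ratio=True) == 200.0

    def test_monotone_in_ib4(self):
        rng = np.random.default_rng(0)
        icam2 = rng.random((6, 10, 10)) > 0.5
        ib4_small = icam2 & (rng.random(icam2.shape) > 0.5)
        ib4_big = ib4_small | (icam2 & (rng.random(icam2.shape) > 0.5))
        assert perfusion_percentage(mask(ib4_big), mask(icam2)) >= perfusion_percentage(
            mask(ib4_small), mask(icam2)
        )

    def test_empty_icam2_errors(self):
        with pytest.raises(ValueError, match="ICAM2"):
            perfusion_percentage(mask(np.ones((2, 2, 2))), mask(np.zeros((2, 2, 2))))

    @pytest.mark.parametrize("seed", range(5))
    def test_tracks_true_perfused_fraction(self, seed):
        """Measured perfusion follows the planted perfused volume fraction."""
        tree = synth.generate_vascular_tree(
            (35.0, 150.0, 150.0), 150, seed=seed + 50,
            segment_length_um=(20.0, 34.0), min_separation_um=6.0, min_clearance_um=8.0,
        )
        tree = synth.set_perfused_fraction(tree, 0.7, seed=seed)
        ds = synth.rasterize(tree, noise_sd=200.0, seed=seed)
        true_pct = 100.0 * (
            ds.true_masks["perfusion"].values & ds.true_masks["endothelium"].values
        ).sum() / ds.true_masks["endothelium"].values.sum()
        ec = multiscale_multilevel_segment(ds.channels["endothelium"], STRUCTURAL_SEG_PARAMS)
        ib4 = multiscale_multilevel_segment(ds.channels["perfusion"], STRUCTURAL_SEG_PARAMS)
        measured = perfusion_percentage(ib4, ec)
        assert abs(measured - true_pct) <= 5.0


class TestDextran:
    def test_contained_tracer_gives_zero(self, small_dataset):
        vessels = small_dataset.true_masks["perfusion"]
        tissue = vessels.with_values(np.ones(vessels.shape, dtype=bool))
        assert extravascular_dextran_percentage(vessels, vessels, tissue) == 0.0

    def test_everything_leaked(self):
        tissue = mask(np.ones((4, 4, 4)))
        nothing = mask(np.zeros((4, 4, 4)))
        assert extravascular_dextran_percentage(tissue, nothing, tissue) == 100.0

    def test_planted_leak_blobs_counted_exactly(self):
        vessels = np.zeros((10, 20, 20), dtype=bool)
        vessels[:, :5] = True
        dextran = vessels.copy()
        dextran[4:6, 10:14, 10:14] = True  # 2*4*4 = 32 leaked voxels
        tissue = np.ones_like(vessels)
        pct = extravascular_dextran_percentage(mask(dextran), mask(vessels), mask(tissue))
        assert pct == pytest.approx(100.0 * 32 / 4000)


class TestHypoxiaStats:
    def test_constant_field(self):
        grid = VoxelGrid(np.full((4, 4, 4), 1500.0), (1, 1, 1))
        tissue = mask(np.ones((4, 4, 4)))
        hs = hypoxia_stats(grid, tissue, n_bins=8)
        assert hs.mfi == 1500.0
        assert (hs.histogram > 0).sum() == 1
        assert hs.histogram.sum() == 64

    def test_longer_decay_raises_mfi(self, small_dataset):
        perf = small_dataset.true_masks["perfusion"]
        tissue = perf.with_values(np.ones(perf.shape, dtype=bool))
        short = synth.make_hypoxia_field(perf, decay_length_um=10.0)
        long_ = synth.make_hypoxia_field(perf, decay_length_um=40.0)
        assert hypoxia_stats(long_, tissue).mfi < hypoxia_stats(short, tissue).mfi

    def test_empty_tissue_errors(self):
        grid = VoxelGrid(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="tissue"):
            hypoxia_stats(grid, mask(np.zeros((2, 2, 2))))


class TestDiffusionDistance:
    def test_plane_source_closed_form(self):
        vessels = np.zeros((10, 5, 5), dtype=bool)
        vessels[0] = True
        stats = diffusion_distance_stats(mask(vessels))
        d = stats.distances_um.reshape(9, 5, 5)
        for k in range(1, 10):
            assert np.all(d[k - 1] == k)

    def test_vessel_voxels_have_zero_distance_excluded(self):
        vessels = np.zeros((5, 5, 5), dtype=bool)
        vessels[2, 2, 2] = True
        stats = diffusion_distance_stats(mask(vessels))
        assert stats.distances_um.min() > 0  # extravascular voxels only
        assert len(stats.distances_um) == 124

    def test_matches_brute_force_on_20cube(self):
        rng = np.random.default_rng(4)
        vessels = rng.random((20, 20, 20)) < 0.01
        vessels[3, 4, 5] = True
        vs = (2.0, 1.0, 1.0)
        stats = diffusion_distance_stats(mask(vessels, vs))
        coords = np.argwhere(vessels) * np.array(vs)
        free = np.argwhere(~vessels) * np.array(vs)
        brute = np.sqrt(
            ((free[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        assert np.allclose(np.sort(stats.distances_um), np.sort(brute))

    def test_adding_vessels_decreases_mean(self):
        vessels = np.zeros((10, 10, 10), dtype=bool)
        vessels[0, 0, 0] = True
        sparse = diffusion_distance_stats(mask(vessels)).mean_um
        vessels[9, 9, 9] = True
        dense = diffusion_distance_stats(mask(vessels)).mean_um
        assert dense < sparse

    def test_no_vessels_errors(self):
        with pytest.raises(ValueError, match="no vessels"):
            diffusion_distance_stats(mask(np.zeros((3, 3, 3))))


class TestPasArea:
    RULE = {"r": (150, 255), "g": (0, 120), "b": (80, 200)}

    def _image(self, positive_mask):
        img = np.zeros((*positive_mask.shape, 3))
        img[..., 0], img[..., 1], img[..., 2] = 30, 200, 30  # negative colour
        img[positive_mask] = (200, 60, 120)  # PAS-positive colour
        return img

    def test_all_and_none(self):
        tissue = np.ones((20, 20), dtype=bool)
        assert pas_area_percentage(self._image(tissue), self.RULE, tissue) == 100.0
        assert pas_area_percentage(self._image(np.zeros_like(tissue)), self.RULE, tissue) == 0.0

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(1)
        tissue = np.ones((50, 50), dtype=bool)
        positive = rng.random((50, 50)) < 0.3
        pct = pas_area_percentage(self._image(positive), self.RULE, tissue)
        assert pct == pytest.approx(100.0 * positive.sum() / tissue.sum())

    def test_empty_tissue_errors(self):
        with pytest.raises(ValueError, match="tissue"):
            pas_area_percentage(self._image(np.zeros((5, 5), dtype=bool)),
                                self.RULE, np.zeros((5, 5), dtype=bool))
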
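"""Generator ground truth: network statistics, rendering, determinism, I/O."""

import numpy as np
import pytest

from cardiocap3d import synth


def _round_half_up(x):
    return int(np.floor(x + 0.5))


class TestGenerateTree:
    def test_single_segment_network(self):
        g = synth.generate_vascular_tree((30, 60, 60), 1, seed=0)
        assert g.n_segments == 1
        degrees = sorted(n.degree for n in g.nodes)
        assert degrees == [1, 1]

    def test_branching_degrees_are_3_or_4(self, small_tree):
        assert all(n.degree in (1, 3, 4) for n in small_tree.nodes)

    def test_endpoints_coincide_with_nodes(self, small_tree):
        small_tree.validate()  # raises on any endpoint/degree inconsistency

    def test_straight_segments_have_unit_tortuosity(self):
        g = synth.generate_vascular_tree((30, 80, 80), 10, seed=3, tortuosity_amplitude=0.0)
        for s in g.segments:
            assert abs(s.length_um - s.chord_um) < 1e-9

    def test_bowed_segments_are_tortuous(self):
        g = synth.generate_vascular_tree((30, 80, 80), 10, seed=3, tortuosity_amplitude=1.0)
        assert all(s.tortuosity > 1.0 for s in g.segments if len(s.path_um) > 2)

    def test_impossible_packing_raises_capacity_error(self):
        with pytest.raises(synth.CapacityError):
            synth.generate_vascular_tree((10, 20, 20), 500, seed=0)

    def test_study_scale_segment_count(self):
        """~2,500 segments pack into one 350 x 350 x 35 um volume of interest."""
        g = synth.generate_vascular_tree((35, 350, 350), 2500, seed=1)
        assert 2250 <= g.n_segments <= 2750
        g.validate()


class TestPlantSleeves:
    @pytest.mark.parametrize("fraction", [0.0, 0.02, 0.04, 0.07, 0.1, 1.0])
    def test_flag_count_is_rounded_fraction(self, small_tree, fraction):
        g = synth.plant_empty_sleeves(small_tree, fraction, seed=5)
        assert g.n_sleeves == _round_half_up(fraction * g.n_segments)

    def test_sleeves_never_perfused(self, small_tree):
        g = synth.plant_empty_sleeves(small_tree, 0.5, seed=5)
        for s in g.segments:
            assert not (s.is_empty_sleeve and s.is_perfused)

    def test_seeded_choice_is_deterministic(self, small_tree):
        a = synth.plant_empty_sleeves(small_tree, 0.2, seed=9)
        b = synth.plant_empty_sleeves(small_tree, 0.2, seed=9)
        assert [s.is_empty_sleeve for s in a.segments] == [s.is_empty_sleeve for s in b.segments]

    def test_preferred_sleeves_bridge_branch_nodes(self, small_tree):
        g = synth.plant_empty_sleeves(small_tree, seed=2, n_sleeves=2)
        deg_at = {tuple(np.round(n.position_um, 6)): n.degree for n in g.nodes}
        for s in g.segments:
            if s.is_empty_sleeve:
                for end in (s.path_um[0], s.path_um[-1]):
                    assert deg_at[tuple(np.round(end, 6))] >= 3


class TestRasterize:
    def test_membrane_foreground_superset_of_endothelium(self, small_dataset):
        em = small_dataset.true_masks["endothelium"].values
        bm = small_dataset.true_masks["basement_membrane"].values
        assert not (em & ~bm).any()

    def test_sleeve_voxels_only_in_membrane_channel(self):
        tree = synth.generate_well_separated_tree(seed=4)
        tree = synth.plant_empty_sleeves(tree, seed=0, n_sleeves=1)
        sleeve = next(s for s in tree.segments if s.is_empty_sleeve)
        vs = (1.0, 1.0, 1.0)
        em = synth.true_tube_mask(tree, vs, "endothelium")
        bm = synth.true_tube_mask(tree, vs, "basement_membrane")
        only = synth.true_tube_mask(
            synth.VascularGraphTruth(tree.nodes, [sleeve], tree.domain_um), vs, "basement_membrane"
        )
        core = only.values & ~em.values  # sleeve body away from junctions
        assert core.any()
        assert not (core & ~bm.values).any()  # sleeve body lives in the membrane channel

    def test_noise_free_raster_thresholds_to_exact_tubes(self):
        tree = synth.generate_well_separated_tree(seed=2, n_segments_target=6)
        ds = synth.rasterize(tree, (1.0, 1.0, 1.0), psf_sigma_um=0.0, noise_sd=0.0, seed=0)
        tubes = synth.true_tube_mask(tree, (1.0, 1.0, 1.0), "endothelium")
        thresholded = ds.channels["endothelium"].values > (100 + 2000) / 2
        assert np.array_equal(thresholded, tubes.values)

    def test_same_seed_gives_identical_channels(self, small_dataset):
        ds2 = synth.rasterize(small_dataset.truth, noise_sd=200.0, seed=small_dataset.seed)
        for name, grid in small_dataset.channels.items():
            assert np.array_equal(grid.values, ds2.channels[name].values)

    def test_different_seeds_differ(self, small_dataset):
        ds2 = synth.rasterize(small_dataset.truth, noise_sd=200.0, seed=small_dataset.seed + 1)
        assert not np.array_equal(
            ds2.channels["endothelium"].values,
            small_dataset.channels["endothelium"].values,
        )

    def test_thin_tube_raster_warns(self):
        tree = synth.generate_vascular_tree(
            (30, 60, 60), 4, radius_dist=(1.0, 0.0), seed=0
        )
        with pytest.warns(UserWarning, match="smallest tube radius"):
            synth.true_tube_mask(tree, (2.0, 2.0, 2.0), "endothelium")


class TestScatterNuclei:
    def test_zero_density_gives_empty_channel(self, small_tree):
        grid, truth = synth.scatter_nuclei(small_tree, 0.0, seed=1)
        assert not grid.values.any()
        assert len(truth) == 0

    def test_count_matches_poisson_mean(self):
        """Expected count = density x non-sleeve length (Poisson, +/- 3 SD)."""
        tree = synth.generate_well_separated_tree(seed=7, n_segments_target=30)
        total = sum(s.length_um for s in tree.segments)
        density = 0.05
        counts = [
            len(synth.scatter_nuclei(tree, density, seed=s)[1]) for s in range(12)
        ]
        mean = density * total
        assert abs(np.mean(counts) - mean) < 3 * np.sqrt(mean / len(counts))

    def test_truth_list_independent_of_overlap(self):
        # two nuclei forced to overlap still yield two truth entries
        tree = synth.generate_well_separated_tree(seed=3, n_segments_target=2)
        grid, truth = synth.scatter_nuclei(tree, 0.3, nucleus_radius_um=6.0, seed=5)
        assert len(truth) >= 2  # dense draw on a short network overlaps somewhere
        # rendering may merge spheres; the truth list must not
        assert len(truth) == len(np.unique(np.round(truth, 9), axis=0))


class TestHypoxiaField:
    def test_closed_form_values(self):
        mask = np.zeros((1, 1, 50), dtype=bool)
        mask[0, 0, 0] = True
        grid = synth.VoxelGrid(mask, (1.0, 1.0, 1.0))
        field = synth.make_hypoxia_field(grid, decay_length_um=10.0, max_intensity=4000.0)
        assert field.values[0, 0, 0] == 0.0
        assert field.values[0, 0, 10] == pytest.approx(4000 * (1 - np.exp(-1)))
        assert field.values[0, 0, 49] == pytest.approx(4000 * (1 - np.exp(-4.9)))

    def test_monotone_in_distance(self, small_dataset):
        perf = small_dataset.true_masks["perfusion"]
        field = synth.make_hypoxia_field(perf)
        from scipy import ndimage

        d = ndimage.distance_transform_edt(~perf.values, sampling=perf.voxel_size_um)
        order = np.argsort(d.ravel())
        vals = field.values.ravel()[order]
        assert np.all(np.diff(vals) >= -1e-9)

    def test_empty_mask_warns_and_saturates(self):
        grid = synth.VoxelGrid(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))
        with pytest.warns(UserWarning, match="empty vessel mask"):
            field = synth.make_hypoxia_field(grid, 10.0, 3000.0)
        assert (field.values == 3000.0).all()


class TestDatasetIO:
    def test_round_trip_identity(self, small_dataset, tmp_path):
        synth.write_dataset(small_dataset, tmp_path / "ds")
        back = synth.read_dataset(tmp_path / "ds")
        for name, grid in small_dataset.channels.items():
            assert np.array_equal(back.channels[name].values, grid.values)
            assert back.channels[name].voxel_size_um == grid.voxel_size_um
        assert [s.is_empty_sleeve for s in back.truth.segments] == [
            s.is_empty_sleeve for s in small_dataset.truth.segments
        ]
        assert np.allclose(back.nuclei_truth, small_dataset.nuclei_truth)

    def test_missing_channel_errors_with_name(self, small_dataset, tmp_path):
        synth.write_dataset(small_dataset, tmp_path / "ds")
        (tmp_path / "ds" / "perfusion.tif").unlink()
        with pytest.raises(FileNotFoundError, match="perfusion"):
            synth.read_dataset(tmp_path / "ds")

    def test_shape_mismatch_errors(self, small_dataset, tmp_path):
        from cardiocap3d.grid import write_channel_tiff

        synth.write_dataset(small_dataset, tmp_path / "ds")
        bad = synth.VoxelGrid(
            np.zeros((2, 2, 2), dtype=bool), small_dataset.voxel_size_um, "nuclei"
        )
        write_channel_tiff(bad, tmp_path / "ds" / "nuclei.tif")
        with pytest.raises(ValueError, match="shape mismatch"):
            synth.read_dataset(tmp_path / "ds")
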
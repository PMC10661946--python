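"""Fractal dimension and lacunarity against closed forms and enumeration."""

import numpy as np
import pytest

from cardiocap3d import synth
from cardiocap3d.grid import VoxelGrid
from cardiocap3d.fractal import (
    box_count_fd,
    extract_vois,
    gliding_box_lacunarity,
    heterogeneity_sd,
)


def menger_sponge(level: int) -> np.ndarray:
    """Level-n Menger sponge on a 3^n cube (ideal FD = log20/log3)."""
    m = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = m.shape[0]
        out = np.zeros((3 * n,) * 3, dtype=bool)
        for z in range(3):
            for y in range(3):
                for x in range(3):
                    if sum(c == 1 for c in (z, y, x)) < 2:
                        out[z * n : (z + 1) * n, y * n : (y + 1) * n, x * n : (x + 1) * n] = m
        m = out
    return m


def grid(values):
    return VoxelGrid(np.asarray(values, dtype=bool), (1.0, 1.0, 1.0))


class TestBoxCountFD:
    def test_filled_cube_is_three_dimensional(self):
        r = box_count_fd(grid(np.ones((64, 64, 64))), [1, 2, 4, 8, 16])
        assert 2.95 <= r.fd <= 3.05
        assert r.fit_r2 > 0.999

    def test_straight_line_is_one_dimensional(self):
        v = np.zeros((64, 64, 64), dtype=bool)
        v[32, 32, :] = True
        r = box_count_fd(grid(v), [1, 2, 4, 8, 16])
        assert 0.9 <= r.fd <= 1.1

    def test_menger_sponge_matches_similarity_dimension(self):
        r = box_count_fd(grid(menger_sponge(3)), [1, 3, 9, 27])
        assert abs(r.fd - np.log(20) / np.log(3)) < 0.15

    def test_counts_non_decreasing_at_smaller_boxes(self, small_dataset):
        mask = small_dataset.true_masks["endothelium"]
        r = box_count_fd(mask, [1, 2, 4])
        assert list(r.box_counts) == sorted(r.box_counts)  # sizes stored decreasing

    def test_invariant_to_translation_by_box_multiples_and_axis_permutation(self):
        v = np.zeros((32, 32, 32), dtype=bool)
        v[4:12, 8:20, 2:10] = True
        sizes = [1, 2, 4]
        base = box_count_fd(grid(v), sizes)
        shifted = np.roll(v, (4, 8, 4), axis=(0, 1, 2))
        permuted = np.transpose(v, (2, 0, 1))
        assert box_count_fd(grid(shifted), sizes).fd == pytest.approx(base.fd)
        assert box_count_fd(grid(permuted), sizes).fd == pytest.approx(base.fd)

    def test_empty_mask_and_single_size_error(self):
        with pytest.raises(ValueError):
            box_count_fd(grid(np.zeros((8, 8, 8))), [1, 2, 4])
        with pytest.raises(ValueError):
            box_count_fd(grid(np.ones((8, 8, 8))), [4])


class TestLacunarity:
    def test_filled_mask_lambda_exactly_one(self):
        r = gliding_box_lacunarity(grid(np.ones((16, 16, 16))), [2, 4, 8])
        assert all(abs(l - 1.0) < 1e-12 for l in r.lambda_values)

    def test_lambda_at_least_one(self, small_dataset):
        r = gliding_box_lacunarity(small_dataset.true_masks["endothelium"], [2, 4])
        assert all(l >= 1.0 for l in r.lambda_values)

    def test_octant_fixture_matches_exhaustive_enumeration(self):
        v = np.zeros((8, 8, 8), dtype=bool)
        v[:4, :4, :4] = True
        r = gliding_box_lacunarity(grid(v), [4])
        masses = [
            v[z : z + 4, y : y + 4, x : x + 4].sum()
            for z in range(5)
            for y in range(5)
            for x in range(5)
        ]
        masses = np.array(masses, dtype=float)
        expected = 1 + masses.var() / masses.mean() ** 2
        assert r.lambda_values[0] == pytest.approx(expected, abs=1e-12)

    def test_homogeneous_mask_lambda_decays_with_box_size(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            v = rng.random((24, 24, 24)) < 0.4
            r = gliding_box_lacunarity(grid(v), [2, 12])
            assert r.lambda_values[-1] < r.lambda_values[0]
            assert r.lambda_values[-1] < 1.05

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="zero"):
            gliding_box_lacunarity(grid(np.zeros((8, 8, 8))), [2])


class TestExtractVois:
    def test_whole_volume_identity_crop(self, small_dataset):
        vol = small_dataset.true_masks["endothelium"]
        crops = extract_vois(vol, 1, vol.domain_um, seed=0)
        assert np.array_equal(crops[0].values, vol.values)

    def test_default_voi_voxel_shape(self):
        vol = VoxelGrid(np.zeros((18, 600, 600), dtype=bool), (2.0, 0.6, 0.6))
        crops = extract_vois(vol, 1, (35.0, 350.0, 350.0), seed=1)
        assert crops[0].shape == (18, 583, 583)

    def test_seeded_corners_reproducible_and_disjoint(self, small_dataset):
        vol = small_dataset.true_masks["endothelium"]
        size = tuple(d / 3 for d in vol.domain_um)
        a = extract_vois(vol, 3, size, seed=7)
        b = extract_vois(vol, 3, size, seed=7)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.values, cb.values)

    def test_oversized_voi_errors(self, small_dataset):
        vol = small_dataset.true_masks["endothelium"]
        with pytest.raises(ValueError, match="larger"):
            extract_vois(vol, 1, tuple(2 * d for d in vol.domain_um))


class TestHeterogeneity:
    def test_identical_values_zero_sd(self):
        s = heterogeneity_sd([2.7, 2.7, 2.7])
        assert s.sd == 0.0 and s.cv == 0.0

    def test_two_values_closed_form(self):
        assert heterogeneity_sd([1.0, 3.0]).sd == pytest.approx(np.sqrt(2))

    def test_matches_two_pass_formula(self):
        vals = [2.7, 2.9, 2.65, 2.8, 2.75]
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert heterogeneity_sd(vals).sd == pytest.approx(sd)

    def test_mixed_density_hearts_spread_more_than_homogeneous(self):
        """Across-VOI FD spread: one generator density vs a mix of two."""
        wins = 0
        for seed in range(10):
            homo, mixed = [], []
            for i in range(5):
                t = synth.generate_vascular_tree((30, 100, 100), 60, seed=seed * 31 + i)
                homo.append(box_count_fd(synth.true_tube_mask(t, (1.5, 1.5, 1.5))).fd)
                n2 = 20 if i % 2 else 100
                t2 = synth.generate_vascular_tree((30, 100, 100), n2, seed=seed * 57 + i)
                mixed.append(box_count_fd(synth.true_tube_mask(t2, (1.5, 1.5, 1.5))).fd)
            wins += heterogeneity_sd(mixed).sd > heterogeneity_sd(homo).sd
        assert wins >= 9
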
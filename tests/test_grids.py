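"""Canonical-grid conformation: reorientation, resampling, cropping, slicing."""

import nibabel as nib
import numpy as np
import pytest

from adenovol import (
    GridSpec,
    VolumeGrid,
    conform_grid,
    load_volume,
    normalize_intensity,
    preprocess_image,
    reorient_ras,
    resample_isotropic,
    save_volume,
    slice_coronal,
    stack_coronal,
)
from adenovol.grids import is_ras

from conftest import ras_volume


def las_volume(data, spacing=1.0):
    """Left-handed first axis: x decreases toward the Right."""
    aff = np.diag([-spacing, spacing, spacing, 1.0])
    aff[0, 3] = spacing * (data.shape[0] - 1)  # keep world extent positive-ish
    return VolumeGrid(data, aff)


class TestReorient:
    def test_ras_input_unchanged(self, rng):
        v = ras_volume(rng.normal(size=(8, 9, 10)))
        out = reorient_ras(v)
        assert np.array_equal(out.data, v.data)
        assert np.allclose(out.affine, v.affine)

    def test_las_flips_first_axis_and_preserves_world_coords(self, rng):
        data = rng.normal(size=(8, 9, 10))
        v = las_volume(data)
        out = reorient_ras(v)
        assert is_ras(out)
        assert np.array_equal(out.data, data[::-1])
        # corner voxel (0,0,0) of the input lives at (7,0,0) of the output
        assert np.allclose(v.world_coords((0, 0, 0)), out.world_coords((7, 0, 0)))

    def test_permuted_axes_recovered(self, rng):
        data = rng.normal(size=(6, 7, 8))
        # axes stored as (S, R, A): voxel axis 0 -> world z, 1 -> x, 2 -> y
        aff = np.zeros((4, 4))
        aff[2, 0] = aff[0, 1] = aff[1, 2] = 1.0
        aff[3, 3] = 1.0
        out = reorient_ras(VolumeGrid(data, aff))
        assert is_ras(out)
        assert out.shape == (7, 8, 6)
        assert np.allclose(out.data, data.transpose(1, 2, 0))

    def test_idempotent(self, rng):
        v = las_volume(rng.normal(size=(8, 8, 8)))
        once = reorient_ras(v)
        twice = reorient_ras(once)
        assert np.array_equal(once.data, twice.data)
        assert np.allclose(once.affine, twice.affine)

    def test_centroid_world_coordinate_preserved(self, rng):
        data = rng.uniform(size=(9, 8, 7)) + 0.1
        v = las_volume(data, spacing=2.0)
        out = reorient_ras(v)

        def centroid_world(vol):
            idx = np.indices(vol.shape).reshape(3, -1)
            w = vol.data.ravel()
            com = (idx * w).sum(axis=1) / w.sum()
            return vol.world_coords(com)

        assert np.allclose(centroid_world(v), centroid_world(out), atol=1e-6)

    def test_oblique_rejected(self, rng):
        theta = np.deg2rad(30)
        aff = np.eye(4)
        aff[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        with pytest.raises(ValueError, match="obliquity"):
            reorient_ras(VolumeGrid(rng.normal(size=(8, 8, 8)), aff))

    def test_singular_affine_rejected(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(ValueError):
            VolumeGrid(np.zeros((8, 8, 8)), aff)


class TestResample:
    def test_exact_ratio_doubles_shape(self, rng):
        v = ras_volume(rng.normal(size=(16, 16, 16)), spacing=2.0)
        out = resample_isotropic(v, 1.0)
        assert out.shape == (32, 32, 32)
        assert np.allclose(out.spacing, 1.0)

    def test_constant_volume_stays_constant(self):
        v = ras_volume(np.full((12, 12, 12), 3.5), spacing=2.0)
        out = resample_isotropic(v, 1.0)
        assert np.allclose(out.data, 3.5)

    def test_mask_values_stay_binary_and_volume_preserved(self):
        # ellipsoid radii (10, 8, 6) mm on a 2 mm grid
        spec_shape = 32
        ax = (np.arange(spec_shape) + 0.5) * 2.0
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        c = spec_shape  # center at 32 mm
        mask = (
            ((x - c) / 10.0) ** 2 + ((y - c) / 8.0) ** 2 + ((z - c) / 6.0) ** 2 <= 1
        ).astype(np.uint8)
        v = ras_volume(mask.astype(float), spacing=2.0)
        out = resample_isotropic(v, 1.0, is_mask=True)
        assert set(np.unique(out.data)) <= {0, 1}
        vol_before = mask.sum() * 8.0
        vol_after = out.data.sum() * 1.0
        analytic = 4 / 3 * np.pi * 10 * 8 * 6
        assert abs(vol_after - vol_before) / analytic < 0.05
        assert abs(vol_after - analytic) / analytic < 0.05

    def test_degenerate_shape_rejected(self):
        v = ras_volume(np.zeros((1, 8, 8)))
        with pytest.raises(ValueError, match="degenerate"):
            resample_isotropic(v, 1.0)

    def test_field_of_view_preserved(self, rng):
        v = ras_volume(rng.normal(size=(10, 14, 20)), spacing=2.0)
        out = resample_isotropic(v, 0.5)
        fov_in = np.asarray(v.shape) * v.spacing
        fov_out = np.asarray(out.shape) * out.spacing
        assert np.all(np.abs(fov_in - fov_out) <= v.spacing)


class TestConform:
    def test_pad_centers_content(self, rng):
        data = rng.normal(size=(8, 8, 8))
        v = ras_volume(data)
        out = conform_grid(v, GridSpec(shape=(16, 16, 16)))
        assert out.shape == (16, 16, 16)
        assert np.array_equal(out.data[4:12, 4:12, 4:12], data)
        # padding uses the image minimum
        assert out.data[0, 0, 0] == pytest.approx(data.min())

    def test_crop_center(self, rng):
        data = rng.normal(size=(20, 20, 20))
        out = conform_grid(ras_volume(data), GridSpec(shape=(12, 12, 12)))
        assert np.array_equal(out.data, data[4:16, 4:16, 4:16])

    def test_pad_then_crop_round_trip(self, rng):
        data = rng.normal(size=(9, 11, 13))
        v = ras_volume(data)
        padded = conform_grid(v, GridSpec(shape=(16, 16, 16)))
        back = conform_grid(padded, GridSpec(shape=(9, 11, 13)))
        assert np.array_equal(back.data, data)

    def test_world_coordinates_preserved_under_crop_and_pad(self, rng):
        data = rng.normal(size=(10, 10, 10))
        v = ras_volume(data)
        out = conform_grid(v, GridSpec(shape=(14, 14, 14)))
        # voxel (2,2,2) of the padded grid is voxel (0,0,0) of the input
        assert np.allclose(out.world_coords((2, 2, 2)), v.world_coords((0, 0, 0)))

    def test_mask_pads_with_zero(self):
        mask = np.ones((8, 8, 8))
        out = conform_grid(ras_volume(mask), GridSpec(shape=(12, 12, 12)), is_mask=True)
        assert out.data.sum() == 512
        assert out.data[0, 0, 0] == 0


class TestNormalize:
    def test_zero_mean_unit_sd(self, rng):
        out = normalize_intensity(ras_volume(rng.normal(2.0, 5.0, size=(10, 10, 10))))
        assert abs(out.data.mean()) < 1e-9
        assert abs(out.data.std() - 1) < 1e-9

    def test_constant_maps_to_zero(self):
        out = normalize_intensity(ras_volume(np.full((8, 8, 8), 7.0)))
        assert np.all(out.data == 0)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(10, 10, 10))
        a = normalize_intensity(ras_volume(data))
        b = normalize_intensity(ras_volume(3.7 * data + 11.0))
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestCoronalSlicing:
    def test_slice_count_and_shape(self, rng):
        v = ras_volume(rng.normal(size=(16, 12, 16)))
        slices = slice_coronal(v)
        assert len(slices) == 12
        assert all(s.data.shape == (16, 16) for s in slices)

    def test_round_trip(self, rng):
        v = ras_volume(rng.normal(size=(8, 10, 12)))
        back = stack_coronal(slice_coronal(v), affine=v.affine)
        assert np.array_equal(back.data, v.data)

    def test_slice_content_matches_anterior_index(self, rng):
        v = ras_volume(rng.normal(size=(8, 10, 12)))
        slices = slice_coronal(v)
        for k in (0, 5, 9):
            assert np.array_equal(slices[k].data, v.data[:, k, :])

    def test_non_ras_rejected(self, rng):
        aff = np.diag([-1.0, 1.0, 1.0, 1.0])
        v = VolumeGrid(rng.normal(size=(8, 8, 8)), aff)
        with pytest.raises(ValueError, match="RAS"):
            slice_coronal(v)


class TestFullChainAndIO:
    def test_preprocess_deterministic(self, rng, tmp_path):
        data = rng.normal(size=(20, 24, 18))
        v = las_volume(data, spacing=2.0)
        spec = GridSpec(shape=(32, 32, 32), spacing=1.0)
        a = preprocess_image(v, spec)
        b = preprocess_image(las_volume(data.copy(), spacing=2.0), spec)
        assert np.array_equal(a.data, b.data)
        assert a.shape == (32, 32, 32)
        assert abs(a.data.mean()) < 1e-9

    def test_nifti_round_trip(self, rng, tmp_path):
        v = ras_volume(rng.normal(size=(8, 9, 10)))
        p = tmp_path / "vol.nii.gz"
        save_volume(v, p)
        back = load_volume(p)
        assert np.allclose(back.data, v.data)
        assert np.allclose(back.affine, v.affine)
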
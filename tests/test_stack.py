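"""Stack preprocessing: loading, surface detection, flattening, profiles."""

import numpy as np
import pytest

import stromalight as sl
from stromalight.errors import (DetectionError, FormatError, PreconditionError,
                                RangeError)


def _stack(volume, vxy=1.6, vz=1.0):
    return sl.CorneaStack(volume, vxy, vz)


class TestLoadAndInvariants:
    def test_tiff_roundtrip_preserves_shape_and_values(self, tmp_path, flat_stack_spec):
        stack, _ = sl.simulate_stack(flat_stack_spec)
        path = tmp_path / "stack.tiff"
        sl.save_stack(stack, path)
        loaded = sl.load_stack(path, 1.6, 1.0)
        assert loaded.n_slices == stack.n_slices
        np.testing.assert_allclose(loaded.volume, stack.volume, rtol=1e-6)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            sl.load_stack(tmp_path / "nope.tiff", 1.6, 1.0)

    def test_2d_image_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "flat.tiff"
        tifffile.imwrite(path, np.ones((64, 64), dtype=np.float32))
        with pytest.raises(FormatError):
            sl.load_stack(path, 1.6, 1.0)

    def test_negative_values_rejected_not_clamped(self):
        vol = np.ones((32, 32, 32))
        vol[3, 4, 5] = -1.0
        with pytest.raises(FormatError, match="negative"):
            _stack(vol)

    @pytest.mark.parametrize("vxy,vz", [(0.0, 1.0), (1.6, -2.0)])
    def test_nonpositive_voxel_sizes_rejected(self, vxy, vz):
        with pytest.raises(FormatError):
            _stack(np.ones((32, 32, 32)), vxy, vz)


class TestDetectSurface:
    def test_flat_surface_recovered_exactly(self, flat_stack_spec):
        stack, truth = sl.simulate_stack(flat_stack_spec)
        surface = sl.detect_surface(stack)
        assert np.all(np.abs(surface.positions - 30.0) <= 0.5)

    def test_tilted_surface_recovered_within_one_slice_rms(self):
        spec = sl.SimulationSpec(
            mode="stack", l_s=108.0, z_max=300.0, z_step=1.0, lateral_size=64,
            surface_base_slices=25, tilt_x_slices=20.0,
            speckle="gamma", speckle_shape=25.0, seed=8,
            sigma0=0.0, sigma_floor=0.0)
        stack, truth = sl.simulate_stack(spec)
        surface = sl.detect_surface(stack)
        err = surface.positions - np.asarray(truth["surface_positions"])
        assert np.sqrt(np.mean(err**2)) <= 1.0

    def test_curved_surface_recovered_with_speckle(self):
        spec = sl.SimulationSpec(
            mode="stack", l_s=108.0, z_max=300.0, z_step=1.0, lateral_size=64,
            surface_base_slices=20, tilt_x_slices=10.0, tilt_y_slices=5.0,
            curvature_slices=8.0, speckle="gamma", speckle_shape=25.0, seed=9,
            sigma0=0.0, sigma_floor=0.0)
        stack, truth = sl.simulate_stack(spec)
        surface = sl.detect_surface(stack)
        err = surface.positions - np.asarray(truth["surface_positions"])
        assert np.sqrt(np.mean(err**2)) <= 1.0

    def test_all_zero_stack_fails_detection(self):
        with pytest.raises(DetectionError):
            sl.detect_surface(_stack(np.zeros((64, 48, 48))))

    def test_even_savgol_window_rejected(self, flat_stack_spec):
        stack, _ = sl.simulate_stack(flat_stack_spec)
        with pytest.raises(PreconditionError):
            sl.detect_surface(stack, savgol_window=30)


class TestFlattenStack:
    def test_flat_stack_with_zero_surface_is_identity(self):
        vol = np.random.default_rng(0).gamma(5, 1, (32, 32, 32))
        stack = _stack(vol)
        surface = sl.SurfaceMap(np.zeros((32, 32)))
        out = sl.flatten_stack(stack, surface)
        np.testing.assert_array_equal(out.volume, vol)

    def test_tilted_stack_flattens_to_plane(self):
        spec = sl.SimulationSpec(
            mode="stack", l_s=108.0, z_max=300.0, z_step=1.0, lateral_size=64,
            surface_base_slices=25, tilt_x_slices=20.0, speckle=None,
            sigma0=0.0, sigma_floor=0.0, seed=8)
        stack, _ = sl.simulate_stack(spec)
        surface = sl.detect_surface(stack)
        flat = sl.flatten_stack(stack, surface)
        resurf = sl.detect_surface(flat)
        assert np.sqrt(np.mean(resurf.positions**2)) <= 1.0

    def test_flattening_idempotent(self):
        spec = sl.SimulationSpec(
            mode="stack", l_s=108.0, z_max=300.0, z_step=1.0, lateral_size=64,
            surface_base_slices=25, tilt_x_slices=12.0, speckle=None,
            sigma0=0.0, sigma_floor=0.0, seed=4)
        stack, _ = sl.simulate_stack(spec)
        flat1 = sl.flatten_stack(stack, sl.detect_surface(stack))
        surf2 = sl.detect_surface(flat1)
        flat2 = sl.flatten_stack(flat1, surf2)
        # second surface is already at z=0; second flatten changes nothing
        assert np.sqrt(np.nanmean(surf2.positions**2)) <= 1.0
        np.testing.assert_allclose(
            np.nanmean(flat2.volume, axis=(1, 2))[:250],
            np.nanmean(flat1.volume, axis=(1, 2))[:250], rtol=0.05)

    def test_nan_surface_column_excluded_others_unchanged(self):
        vol = np.random.default_rng(1).gamma(5, 1, (32, 32, 32))
        stack = _stack(vol)
        pos = np.zeros((32, 32))
        pos[5, 7] = np.nan
        out = sl.flatten_stack(stack, sl.SurfaceMap(pos))
        assert np.all(np.isnan(out.volume[:, 5, 7]))
        mask = np.ones((32, 32), bool)
        mask[5, 7] = False
        np.testing.assert_array_equal(out.volume[:, mask], vol[:, mask])


class TestExtractStromaAndProfile:
    def test_offset_arithmetic(self):
        vol = np.ones((600, 32, 32))
        stack = _stack(vol)
        sub = sl.extract_stroma(stack, anterior_offset_um=50.0, posterior_offset_um=0.0)
        assert sub.n_slices == 550

    def test_offsets_exceeding_depth_raise(self):
        stack = _stack(np.ones((100, 32, 32)))
        with pytest.raises(RangeError):
            sl.extract_stroma(stack, anterior_offset_um=60.0, posterior_offset_um=50.0)

    def test_epithelium_excluded_from_extracted_profile(self, flat_stack_spec):
        stack, truth = sl.simulate_stack(flat_stack_spec)
        flat = sl.flatten_stack(stack, sl.detect_surface(stack))
        stroma = sl.extract_stroma(flat, anterior_offset_um=60.0)
        profile = sl.compute_depth_profile(stroma)
        # anterior value must match the stromal (not 2x epithelial) scale
        spec = flat_stack_spec
        stromal_at_10um = spec.signal(np.array([10.0]))[0]
        assert abs(profile.a[0] - stromal_at_10um) / stromal_at_10um < 0.10

    def test_constant_stack_gives_constant_profile(self):
        profile = sl.compute_depth_profile(_stack(np.full((50, 32, 32), 7.0)))
        np.testing.assert_array_equal(profile.a, 7.0)
        np.testing.assert_allclose(profile.z, np.arange(50) * 1.0)
        assert profile.z_max == 50.0

    def test_profile_linear_in_amplitude(self):
        vol = np.random.default_rng(3).gamma(4, 2, (40, 32, 32))
        p1 = sl.compute_depth_profile(_stack(vol))
        p2 = sl.compute_depth_profile(_stack(2.5 * vol))
        np.testing.assert_allclose(p2.a, 2.5 * p1.a, rtol=1e-12)

    def test_half_masked_slice_averages_remaining_pixels(self):
        vol = np.full((40, 32, 32), 4.0)
        vol[10, :16, :] = np.nan
        vol[10, 16:, :] = 6.0
        profile = sl.compute_depth_profile(_stack(vol))
        assert profile.a[10] == 6.0
        assert profile.n_pixels_averaged[10] == 16 * 32

    def test_noiseless_pipeline_matches_closed_form(self, flat_stack_spec):
        """Flat noiseless stack: flatten + extract + average reproduces the
        exponential-decay signal to 1e-6 relative accuracy."""
        stack, _ = sl.simulate_stack(flat_stack_spec)
        flat = sl.flatten_stack(stack, sl.detect_surface(stack))
        stroma = sl.extract_stroma(flat, anterior_offset_um=50.0)
        profile = sl.compute_depth_profile(stroma)
        spec = flat_stack_spec
        expected = spec.signal(profile.z)  # origin: stroma starts at epi end
        np.testing.assert_allclose(profile.a, expected, rtol=1e-6)
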
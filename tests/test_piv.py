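"""PIV: correlation core, multipass accuracy, outlier filtering."""

import numpy as np
import numpy.fft as fft
import pytest
from scipy.ndimage import fourier_shift

from nucleostrain import (DisplacementField, ImageStack, PIVConfig,
                          correlate_window, displacement_sequence,
                          filter_outliers, multipass_piv, nucleus_mask)
from nucleostrain.errors import PIVConfigError, SegmentationError


def subpixel_shift(frame, dy, dx):
    return fft.ifft2(fourier_shift(fft.fft2(frame), (dy, dx))).real


class TestCorrelateWindow:
    def test_identical_patches_zero_shift(self, texture):
        patch = texture[32:64, 32:64]
        du, dv, snr = correlate_window(patch, patch)
        assert du == pytest.approx(0.0, abs=1e-6)
        assert dv == pytest.approx(0.0, abs=1e-6)
        assert snr > 1.0

    def test_integer_shift_exact_peak(self, texture):
        # window slid opposite to the pattern motion: content moved (3, -2)
        ref = texture[40:72, 40:72]
        tgt = texture[40 + 2:72 + 2, 40 - 3:72 - 3]
        du, dv, _ = correlate_window(ref, tgt)
        assert round(du) == 3 and round(dv) == -2

    def test_half_pixel_shift_recovered(self, texture):
        # band-limited resampling oracle: known 0.5 px shift
        shifted = subpixel_shift(texture, 0.0, 0.5)
        errs = []
        for cy in range(24, 104, 16):
            for cx in range(24, 104, 16):
                du, dv, _ = correlate_window(texture[cy - 16:cy + 16,
                                                     cx - 16:cx + 16],
                                             shifted[cy - 16:cy + 16,
                                                     cx - 16:cx + 16])
                errs.append(du - 0.5)
        assert abs(np.mean(errs)) < 0.1

    def test_constant_patch_rejected(self):
        flat = np.zeros((16, 16))
        with pytest.raises(ValueError, match="constant"):
            correlate_window(flat, flat)


class TestMultipass:
    def test_identical_frames_zero_field(self, rng):
        frame = rng.random((128, 128))  # fully textured, no flat regions
        f = multipass_piv(frame, frame)
        assert np.allclose(f.u, 0.0, atol=1e-6)
        assert np.allclose(f.v, 0.0, atol=1e-6)
        assert f.valid.all()

    def test_default_grid_spacing_is_4px(self, rng):
        frame = rng.random((256, 256))
        f = multipass_piv(frame, frame)
        assert np.allclose(np.diff(f.grid_x), 4.0)
        assert np.allclose(np.diff(f.grid_y), 4.0)

    def test_subpixel_accuracy_bias_and_rmse(self, texture):
        # noise-free uniform sub-pixel shifts in [-1, 1] px
        biases, rmses = [], []
        for s in np.linspace(-1.0, 1.0, 9):
            shifted = subpixel_shift(texture, 0.0, s)
            f = multipass_piv(texture, shifted)
            interior = f.u[4:-4, 4:-4]
            biases.append(abs(interior.mean() - s))
            rmses.append(np.sqrt(((interior - s) ** 2).mean()))
        assert max(biases) < 0.05
        assert max(rmses) < 0.15

    def test_translation_equivariance(self, texture):
        # rolling both frames by one grid period (8 px) must reproduce the
        # same vectors at the correspondingly shifted nodes
        shifted = subpixel_shift(texture, 0.0, 0.4)
        f0 = multipass_piv(texture, shifted)
        f1 = multipass_piv(np.roll(texture, (8, 8), (0, 1)),
                           np.roll(shifted, (8, 8), (0, 1)))
        np.testing.assert_allclose(f1.u[4:-4, 4:-4], f0.u[2:-6, 2:-6],
                                   atol=1e-3)
        np.testing.assert_allclose(f1.v[4:-4, 4:-4], f0.v[2:-6, 2:-6],
                                   atol=1e-3)

    def test_swap_negates_displacement(self, rendered_pair):
        spec, stack, _ = rendered_pair
        mask = nucleus_mask(spec)
        fwd = multipass_piv(stack.frames[0], stack.frames[1], mask=mask)
        rev = multipass_piv(stack.frames[1], stack.frames[0], mask=mask)
        sel = fwd.valid & rev.valid
        assert np.abs(fwd.u[sel] + rev.u[sel]).mean() < 0.1
        assert np.abs(fwd.v[sel] + rev.v[sel]).mean() < 0.1

    def test_phantom_recovery_rmse(self, rendered_pair, peak_field):
        spec, stack, truth = rendered_pair
        f = peak_field
        gx, gy = np.meshgrid(f.grid_x, f.grid_y)
        u_t, v_t = truth.displacement_fn(gx * spec.pixel_size,
                                         gy * spec.pixel_size,
                                         stack.timestamps[1])
        u_t = u_t / spec.pixel_size
        v_t = v_t / spec.pixel_size
        sel = f.valid
        rmse = np.sqrt(np.mean((f.u[sel] - u_t[sel]) ** 2
                               + (f.v[sel] - v_t[sel]) ** 2))
        assert rmse < 0.15

    def test_frame_smaller_than_window_rejected(self, rng):
        with pytest.raises(PIVConfigError):
            multipass_piv(rng.random((24, 24)), rng.random((24, 24)))


class TestFilterOutliers:
    @staticmethod
    def _uniform_field(n=12, value=1.0):
        g = np.arange(n) * 4.0 + 8.0
        shape = (n, n)
        return DisplacementField(
            grid_x=g, grid_y=g, u=np.full(shape, value),
            v=np.full(shape, value), valid=np.ones(shape, bool),
            snr=np.full(shape, 10.0))

    def test_uniform_field_untouched(self):
        f = filter_outliers(self._uniform_field(), PIVConfig())
        assert f.valid.all()

    def test_single_spike_replaced_by_neighbor_median(self):
        f = self._uniform_field()
        f.u[5, 5] = 10.0
        out = filter_outliers(f, PIVConfig())
        assert not out.valid[5, 5]
        assert out.valid.sum() == f.valid.size - 1
        assert out.u[5, 5] == pytest.approx(1.0)

    def test_planted_outliers_detected(self, rng):
        n = 24
        g = np.arange(n) * 4.0 + 8.0
        yy, xx = np.mgrid[0:n, 0:n]
        u = 0.5 * np.sin(xx / 6.0)  # smooth base field
        v = 0.5 * np.cos(yy / 6.0)
        planted = np.zeros((n, n), bool)
        idx = rng.choice(n * n, size=int(0.05 * n * n), replace=False)
        planted.ravel()[idx] = True
        u = u + np.where(planted, rng.choice([-1, 1], (n, n)) * 6.0, 0.0)
        f = DisplacementField(grid_x=g, grid_y=g, u=u, v=v,
                              valid=np.ones((n, n), bool),
                              snr=np.full((n, n), 10.0))
        out = filter_outliers(f, PIVConfig())
        caught = (~out.valid) & planted
        false_pos = (~out.valid) & ~planted
        assert caught.sum() >= 0.95 * planted.sum()
        assert false_pos.sum() < 0.02 * (~planted).sum()


class TestSequence:
    def test_static_stack_all_zero(self, texture):
        stack = ImageStack(frames=np.stack([texture] * 3),
                           timestamps=np.arange(3) * 0.25)
        fields = displacement_sequence(stack)
        assert len(fields) == 2
        for f in fields:
            assert np.allclose(f.u, 0.0, atol=1e-6)

    def test_empty_mask_rejected(self, texture):
        stack = ImageStack(frames=np.stack([texture] * 2),
                           timestamps=np.arange(2) * 0.25)
        with pytest.raises(SegmentationError):
            displacement_sequence(stack, mask=np.zeros_like(texture, bool))

    def test_temporal_profile_follows_creep_recovery(self):
        # PIV magnitude at a fixed node tracks the Kelvin-Voigt g(t)
        import warnings

        from nucleostrain import (PhantomSpec, kelvin_voigt_g,
                                  render_sequence)

        spec = PhantomSpec(image_shape=(128, 128), nucleus_radius_um=6.0,
                           amplitude_um=1.0)
        idx = [0, 88, 100, 119, 140, 180]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, truth = render_sequence(spec, frame_indices=idx)
        mask = nucleus_mask(spec)
        fields = displacement_sequence(stack, mask=mask)
        g = kelvin_voigt_g(stack.timestamps[1:], spec.timing)
        # compare mean in-mask |displacement| ratios against g(t)
        mags = []
        for f in fields:
            m = np.hypot(f.u, f.v)[f.valid]
            mags.append(m.mean())
        mags = np.array(mags)
        ratio = mags / mags.max()
        np.testing.assert_allclose(ratio, g / g.max(), atol=0.05)

    def test_immobile_nucleolus_core_static(self, nucleolus_spec):
        import warnings

        from nucleostrain import render_sequence

        spec = nucleolus_spec
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, _ = render_sequence(spec, frame_indices=[0, 119])
        mask = nucleus_mask(spec)
        f = multipass_piv(stack.frames[0], stack.frames[1], mask=mask,
                          pixel_size=spec.pixel_size)
        gx, gy = np.meshgrid(f.grid_x, f.grid_y)
        r_px = (spec.nucleolus.radius_um * 0.8) / spec.pixel_size
        in_nll = (np.hypot(gx - 128, gy - 128) <= r_px) & np.isfinite(f.u)
        far = (np.hypot(gx - 128, gy - 128)
               > (spec.nucleolus.radius_um + 3.0) / spec.pixel_size)
        far &= f.valid
        assert np.hypot(f.u[in_nll], f.v[in_nll]).mean() < 0.1
        assert np.hypot(f.u[far], f.v[far]).mean() > 0.3
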
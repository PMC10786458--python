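"""Temporal dynamics: image differences, Kelvin-Voigt fits, tracking,
kymographs, border profiles and fiber strain."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleostrain import (CHCSpec, ImageStack, KelvinVoigtModel,
                          KelvinVoigtTiming, PhantomSpec, TimeSeries,
                          border_profile, fiber_strain, fit_kelvin_voigt,
                          image_difference_series, kelvin_voigt_g, kymograph,
                          nucleus_mask, render_sequence, track_features)
from nucleostrain.kinetics import FeatureTrack


def protocol_times():
    return np.arange(240) * 0.25


def kv_trace(tau_c, tau_r, amplitude=1.0, noise=0.0, rng=None):
    t = protocol_times()
    g = kelvin_voigt_g(t, KelvinVoigtTiming(tau_c=tau_c, tau_r=tau_r))
    y = amplitude * g
    if noise > 0:
        y = y + rng.normal(0.0, noise * y.max(), y.shape)
    return TimeSeries(t=t, value=y)


class TestImageDifference:
    def test_static_stack_all_zero(self, texture):
        stack = ImageStack(frames=np.stack([texture] * 4),
                           timestamps=np.arange(4) * 0.25)
        s = image_difference_series(stack)
        np.testing.assert_array_equal(s.value, 0.0)

    def test_block_change_matches_direct_sum(self, texture):
        frames = np.stack([texture, texture.copy()])
        frames[1, 10:20, 10:30] += 7.0  # b = 200 pixels changed by 7
        mask = np.ones_like(texture, bool)
        s = image_difference_series(
            ImageStack(frames=frames, timestamps=[0.0, 0.25]), mask)
        assert s.value[1] == pytest.approx(200 * 7.0 / mask.sum(), rel=1e-12)

    def test_phantom_rise_and_partial_recovery(self):
        spec = PhantomSpec(image_shape=(128, 128), nucleus_radius_um=6.0,
                           amplitude_um=1.0)
        idx = [0, 90, 110, 119, 150, 239]  # baseline, creep, peak, recovery
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, _ = render_sequence(spec, frame_indices=idx)
        s = image_difference_series(stack, nucleus_mask(spec))
        peak = s.value[3]
        assert s.value[1] < s.value[2] < peak  # rising during stimulation
        assert s.value[-1] < 0.2 * peak       # decays after stimulus off


class TestKelvinVoigtFit:
    def test_paper_creep_time_recovered(self):
        params = fit_kelvin_voigt(kv_trace(0.74, 0.92))
        assert params.tau_c == pytest.approx(0.74, rel=0.01)
        assert params.E == pytest.approx(1.0, rel=0.01)

    def test_paper_relaxation_time_recovered(self):
        params = fit_kelvin_voigt(kv_trace(0.74, 0.92))
        assert params.tau_r == pytest.approx(0.92, rel=0.01)

    @given(tau=st.floats(0.1, 10.0), E=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_roundtrip_identity_noiseless(self, tau, E):
        params = fit_kelvin_voigt(kv_trace(tau, tau, amplitude=1.0 / E))
        assert params.tau_c == pytest.approx(tau, rel=0.01)
        assert params.tau_r == pytest.approx(tau, rel=0.01)
        assert params.E == pytest.approx(E, rel=0.01)

    def test_noisy_recovery_sweep_median_error(self):
        # 5 % plateau noise at 4 fps across the physiological tau range
        rng = np.random.default_rng(1234)
        errs = []
        for tau in (0.2, 0.5, 1.0, 2.0, 5.0):
            for _ in range(100):
                p = fit_kelvin_voigt(kv_trace(tau, tau, noise=0.05, rng=rng))
                errs.append(abs(p.tau_c - tau) / tau)
                errs.append(abs(p.tau_r - tau) / tau)
        assert np.median(errs) < 0.05

    def test_flat_series_flagged(self):
        t = protocol_times()
        rng = np.random.default_rng(0)
        y = rng.normal(0.0, 0.01, t.shape)
        with pytest.warns(UserWarning, match="flat"):
            params = fit_kelvin_voigt(TimeSeries(t=t, value=y))
        assert params.flat

    def test_baseline_subtracted(self):
        s = kv_trace(0.74, 0.92)
        shifted = TimeSeries(t=s.t, value=s.value + 5.0)
        params = fit_kelvin_voigt(shifted)
        assert params.baseline == pytest.approx(5.0, abs=1e-9)
        assert params.tau_c == pytest.approx(0.74, rel=0.01)

    def test_summary_reports_parameters(self):
        res = KelvinVoigtModel(kv_trace(0.74, 0.92)).fit()
        text = res.summary()
        assert "tau_c" in text and "0.74" in text


class TestTracking:
    @staticmethod
    def _blob_stack(positions, shape=(96, 96), sigma=3.0, pixel_size=0.1233):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        frames = [100.0 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2)
                                 / (2 * sigma ** 2)) + 5.0
                  for x, y in positions]
        return ImageStack(frames=np.stack(frames),
                          timestamps=np.arange(len(positions)) * 0.25,
                          pixel_size=pixel_size)

    def test_static_blob_zero_displacement(self):
        stack = self._blob_stack([(48, 48)] * 5)
        tracks = track_features(stack, polarity="bright")
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.displacement_um().max() < 1e-6
        assert np.ptp(tr.area_um2) == 0.0

    def test_translating_blob_velocity(self):
        # 0.05 µm per frame along x
        step_px = 0.05 / 0.1233
        stack = self._blob_stack([(30 + i * step_px, 48) for i in range(12)])
        tracks = track_features(stack, polarity="bright")
        assert len(tracks) == 1
        d = tracks[0].displacement_um()
        vel = np.diff(d).mean() / 0.25
        assert vel == pytest.approx(0.05 / 0.25, rel=0.1)

    def test_rigid_chc_phantom_track(self):
        spec = PhantomSpec(image_shape=(256, 256), nucleus_radius_um=12.0,
                           amplitude_um=1.0,
                           chc=CHCSpec(center_px=(128.0, 128.0),
                                       radius_um=2.5, translation_um=0.8))
        idx = [0, 79, 84, 92, 104, 119, 131, 150, 190]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, _ = render_sequence(spec, frame_indices=idx)
        tracks = track_features(stack, polarity="bright",
                                mask=nucleus_mask(spec), quantile=0.1,
                                min_area_px=200)
        tr = max(tracks, key=lambda t: len(t.t))
        assert len(tr.t) == len(idx)
        # centroid trace follows the Kelvin-Voigt time course
        d = tr.displacement_um()
        g = kelvin_voigt_g(np.asarray(tr.t), spec.timing)
        expected = 0.8 * g
        np.testing.assert_allclose(d, expected, atol=0.06)
        # rigid body: area and axes stay constant within 2 %
        assert np.ptp(tr.area_um2) / np.mean(tr.area_um2) < 0.02
        assert np.ptp(tr.major_um) / np.mean(tr.major_um) < 0.02
        assert np.ptp(tr.minor_um) / np.mean(tr.minor_um) < 0.02


class TestKymograph:
    def test_static_stack_identical_columns(self, texture):
        stack = ImageStack(frames=np.stack([texture] * 3),
                           timestamps=np.arange(3) * 0.25)
        k = kymograph(stack, ((20.0, 30.0), (100.0, 90.0)))
        assert np.all(k[:, 0] == k[:, 1])

    def test_moving_edge_slope(self):
        # a step edge advancing 1 px/frame shows as a unit-slope streak
        n = 12
        frames = np.zeros((n, 32, 64))
        for i in range(n):
            frames[i, :, :20 + i] = 100.0
        stack = ImageStack(frames=frames, timestamps=np.arange(n) * 0.25)
        k = kymograph(stack, ((0.0, 16.0), (63.0, 16.0)))
        edge_pos = np.array([np.argmax(k[:, i] < 50.0) for i in range(n)])
        slope = np.polyfit(np.arange(n), edge_pos, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_zero_length_line_rejected(self, texture):
        stack = ImageStack(frames=texture[None], timestamps=np.zeros(1))
        with pytest.raises(ValueError):
            kymograph(stack, ((10.0, 10.0), (10.0, 10.0)))


class TestBorderProfile:
    @staticmethod
    def _circle_mask(cx, cy, r=40, shape=(128, 128)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2

    def test_static_circle_zero_deviation(self):
        masks = [self._circle_mask(64, 64)] * 4
        prof = border_profile(masks, pixel_size=0.1233)
        assert prof.max_deviation_um() == pytest.approx(0.0, abs=1e-9)

    def test_translated_circle_deviation_one_pixel(self):
        masks = [self._circle_mask(64, 64), self._circle_mask(65, 64)]
        prof = border_profile(masks, pixel_size=0.1233)
        assert prof.max_deviation_um() == pytest.approx(0.1233, abs=0.03)

    def test_internal_deformation_keeps_border_static(self):
        # phantom with the field damped to zero at the lamina: internal
        # chromatin moves while the border stays put (< 200 nm)
        spec = PhantomSpec(image_shape=(192, 192), nucleus_radius_um=9.0,
                           amplitude_um=1.5, border_ramp_um=1.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, _ = render_sequence(spec, frame_indices=[0, 100, 119])
        from nucleostrain import segment_nucleus

        masks = [segment_nucleus(f) for f in stack.frames]
        prof = border_profile(masks, pixel_size=spec.pixel_size)
        assert prof.max_deviation_um() < 0.2
        # and the interior did deform
        s = image_difference_series(stack, nucleus_mask(spec))
        assert s.value[-1] > 1.0


class TestFiberStrain:
    def test_zero_extension_zero_strain(self):
        tr = FeatureTrack(feature_id=0, polarity="bright",
                          t=[20.0, 20.25], centroid_um=[(5.0, 5.0)] * 2)
        fs = fiber_strain(tr)
        np.testing.assert_array_equal(fs.strain, 0.0)

    def test_15_percent_at_published_extension(self):
        # 0.45 µm extension over 3 µm rest length
        tr = FeatureTrack(feature_id=0, polarity="bright",
                          t=[20.0, 30.0],
                          centroid_um=[(5.0, 5.0), (5.45, 5.0)])
        fs = fiber_strain(tr, L0_um=3.0)
        assert fs.strain[-1] == pytest.approx(0.15, abs=1e-12)

    def test_strain_is_scaled_displacement(self):
        pts = [(5.0 + 0.1 * i, 5.0) for i in range(6)]
        tr = FeatureTrack(feature_id=0, polarity="bright",
                          t=[20.0 + 0.25 * i for i in range(6)],
                          centroid_um=pts)
        fs = fiber_strain(tr, L0_um=3.0)
        np.testing.assert_allclose(fs.strain,
                                   tr.displacement_um(0) / 3.0, atol=1e-12)
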
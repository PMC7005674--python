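"""Spot detection, PSF fitting, SNR, drift, registration, colocalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smtirfkit import imaging
from smtirfkit.imaging import SpotDetection
from smtirfkit.simkit import _render_spot


def gaussian_frame(shape=(128, 128), spots=(), background=0.0, sigma=1.3):
    frame = np.full(shape, float(background))
    for y, x, photons in spots:
        _render_spot(frame, y, x, photons, sigma)
    return frame


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        out = imaging.subtract_background(np.full((64, 64), 42.0), 20)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_spot_integral_preserved(self):
        frame = gaussian_frame(spots=[(70.0, 60.0, 500.0)], background=100.0)
        out = imaging.subtract_background(frame, 50)
        yy, xx = np.mgrid[0:128, 0:128]
        box = (np.abs(yy - 70) < 8) & (np.abs(xx - 60) < 8)
        assert out[box].sum() == pytest.approx(500.0, rel=0.05)

    def test_tilted_plane_removed(self):
        yy, xx = np.mgrid[0:128, 0:128]
        plane = 100 + 0.5 * xx + 0.3 * yy
        frame = plane + gaussian_frame(spots=[(70.0, 60.0, 500.0)])
        out = imaging.subtract_background(frame, 50)
        far = (np.abs(yy - 70) > 12) | (np.abs(xx - 60) > 12)
        assert out[far].std() < 0.05 * np.ptp(plane)

    def test_radius_must_fit_image(self):
        with pytest.raises(ValueError):
            imaging.subtract_background(np.zeros((32, 32)), 32)


class TestDetection:
    def test_pure_noise_yields_no_detections(self, rng):
        frame = rng.normal(0.0, 1.0, (128, 128))
        assert imaging.detect_spots(frame, threshold_sigma=6.0) == []

    def test_bright_spot_localized_subpixel(self, rng):
        noise_sd = 2.0
        frame = gaussian_frame(spots=[(40.3, 52.7, 50 * noise_sd * 2 * np.pi * 1.3**2)])
        frame += rng.normal(0, noise_sd, frame.shape)
        spots = imaging.detect_spots(frame, threshold_sigma=6.0)
        assert len(spots) == 1
        assert np.hypot(spots[0].y - 40.3, spots[0].x - 52.7) < 0.1

    def test_two_separated_spots(self):
        frame = gaussian_frame(spots=[(40.0, 40.0, 2000.0), (40.0, 50.0, 2000.0)])
        spots = imaging.detect_spots(frame, threshold_sigma=5.0)
        assert len(spots) == 2


class TestPsfFit:
    def test_noiseless_width_recovered(self):
        frame = gaussian_frame(shape=(21, 21), spots=[(10.3, 9.7, 1000.0)])
        det = imaging.fit_psf(frame, (10, 10))
        assert det.converged
        assert det.psf_sigma_fit == pytest.approx(1.3, abs=1e-3)
        assert det.y == pytest.approx(10.3, abs=1e-3)

    def test_flat_frame_flagged(self):
        det = imaging.fit_psf(np.full((21, 21), 5.0), (10, 10))
        assert not det.converged

    def test_width_filter_drops_wide_spots(self):
        # spots wider than the single-dye reference are aggregates
        ref_sigma = 1.3
        ok = SpotDetection(5, 5, 100.0, 1.35)
        wide = SpotDetection(5, 5, 100.0, 2 * ref_sigma)
        kept = imaging.filter_by_width([ok, wide], reference_sigma=ref_sigma)
        assert kept == [ok]


class TestSnr:
    def test_printed_formula_hand_value(self, rng):
        # (900-100)/sqrt(30^2+10^2) = 800/sqrt(1000) = 25.298
        peak = rng.normal(900, 30, 200_000)
        bg = rng.normal(100, 10, 200_000)
        assert imaging.compute_snr(peak, bg) == pytest.approx(800 / np.sqrt(1000), rel=0.01)

    def test_equal_means_give_zero(self, rng):
        x = rng.normal(100, 5, 1000)
        assert imaging.compute_snr(x, x) == pytest.approx(0.0)

    def test_matches_direct_formula_under_scaling(self, rng):
        peak = rng.normal(500, 20, 5000)
        bg = rng.normal(50, 5, 5000)
        expected = (peak.mean() - bg.mean()) / np.sqrt(peak.var() + bg.var())
        assert imaging.compute_snr(peak, bg) == pytest.approx(expected)
        assert imaging.compute_snr(2 * peak, 2 * bg) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            imaging.compute_snr(np.full(5, 3.0), np.full(5, 1.0))


class TestDrift:
    @staticmethod
    def drifting_stack(slope, n_frames=40, noisy=True):
        rng = np.random.default_rng(0)
        frames = []
        for k in range(n_frames):
            f = gaussian_frame(
                shape=(64, 64),
                spots=[(20 + slope[0] * k, 30 + slope[1] * k, 3000.0),
                       (44 + slope[0] * k, 14 + slope[1] * k, 3000.0),
                       (33 + slope[0] * k, 48 + slope[1] * k, 3000.0)],
                background=100.0,
            )
            frames.append(rng.poisson(f) if noisy else f)
        return np.stack(frames).astype(float)

    def test_known_drift_slope_recovered(self):
        stack = self.drifting_stack((0.1, 0.05))
        track = imaging.estimate_drift(stack)
        k = np.arange(40)
        assert np.polyfit(k, track.dy, 1)[0] == pytest.approx(0.1, abs=0.02)
        assert np.polyfit(k, track.dx, 1)[0] == pytest.approx(0.05, abs=0.02)

    def test_zero_drift_movie(self):
        stack = self.drifting_stack((0.0, 0.0), n_frames=10, noisy=False)
        track = imaging.estimate_drift(stack)
        assert np.all(np.abs(track.dy) <= 0.02)
        assert np.all(np.abs(track.dx) <= 0.02)

    def test_reversed_stack_negates_final_drift(self):
        stack = self.drifting_stack((0.12, -0.08), n_frames=20)
        fwd = imaging.estimate_drift(stack)
        rev = imaging.estimate_drift(stack[::-1])
        assert rev.dy[-1] == pytest.approx(-fwd.dy[-1], abs=0.1)
        assert rev.dx[-1] == pytest.approx(-fwd.dx[-1], abs=0.1)

    def test_featureless_stack_warns(self):
        with pytest.warns(UserWarning, match="featureless"):
            track = imaging.estimate_drift(np.zeros((5, 32, 32)))
        assert track.warning
        assert np.all(track.dy == 0)


class TestRegistration:
    def test_identity_pairs_give_identity(self, rng):
        pts = rng.uniform(5, 120, (10, 2))
        t = imaging.build_registration(pts, pts)
        assert np.allclose(t.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)
        assert t.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_known_affine_recovered_under_noise(self, rng):
        true = np.array([[1.01, 0.02, 3.0], [-0.015, 0.99, -2.0]])
        src = rng.uniform(5, 120, (10, 2))
        dst = np.column_stack([src, np.ones(10)]) @ true.T + rng.normal(0, 0.05, (10, 2))
        t = imaging.build_registration(src, dst)
        # linear part is pinned by the ~100 px lever arm; the translation terms
        # carry the full 0.05-px noise (SD ~ noise/sqrt(n) x lever factor)
        assert np.allclose(t.matrix[:, :2], true[:, :2], atol=1e-2)
        assert np.allclose(t.matrix[:, 2], true[:, 2], atol=0.1)
        assert t.rms_residual < 0.15

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            imaging.build_registration(np.array([[0, 0], [1, 1]]), np.array([[0, 0], [1, 1]]))

    def test_collinear_pairs_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            imaging.build_registration(src, src)

    def test_roundtrip_inverse_is_identity(self, rng):
        true = np.array([[1.02, -0.01, 1.5], [0.02, 0.98, -0.7]])
        src = rng.uniform(5, 120, (12, 2))
        dst = np.column_stack([src, np.ones(12)]) @ true.T
        t = imaging.build_registration(src, dst)
        back = t.inverse().apply(t.apply(src))
        assert np.allclose(back, src, atol=1e-9)


class TestColocalization:
    def test_within_radius_matched(self):
        det = SpotDetection(10.0, 10.0 + 1.5, 100.0, 1.3)
        matched = imaging.colocalize(np.array([[10.0, 10.0]]), [det], radius_px=2.0)
        assert matched[0] == [det]

    def test_beyond_radius_discarded(self):
        det = SpotDetection(10.0, 12.5, 100.0, 1.3)
        matched = imaging.colocalize(np.array([[10.0, 10.0]]), [det], radius_px=2.0)
        assert matched[0] == []

    def test_nearest_locator_wins_and_ties_go_low(self):
        locators = np.array([[10.0, 10.0], [10.0, 13.0]])
        near_second = SpotDetection(10.0, 12.0, 100.0, 1.3)
        tie = SpotDetection(10.0, 11.5, 100.0, 1.3)
        matched = imaging.colocalize(locators, [near_second, tie], radius_px=2.0)
        assert matched[1] == [near_second]
        assert matched[0] == [tie]  # exact tie resolves to the lowest index

    @given(
        dy=st.floats(-5, 5, allow_nan=False),
        dx=st.floats(-5, 5, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_joint_translation(self, dy, dx):
        locators = np.array([[10.0, 10.0], [30.0, 25.0]])
        dets = [SpotDetection(11.0, 10.5, 1.0, 1.3), SpotDetection(29.5, 26.0, 1.0, 1.3)]
        base = imaging.colocalize(locators, dets, radius_px=2.0)
        shifted_dets = [SpotDetection(d.y + dy, d.x + dx, 1.0, 1.3) for d in dets]
        shifted = imaging.colocalize(locators + [dy, dx], shifted_dets, radius_px=2.0)
        for k in base:
            a = np.array([(d.y, d.x) for d in base[k]]).reshape(-1, 2)
            b = np.array([(d.y - dy, d.x - dx) for d in shifted[k]]).reshape(-1, 2)
            assert np.allclose(a, b, atol=1e-9)
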
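"""Spot detection, dual-view registration and aperture photometry."""

import numpy as np
import pytest

from smfret.imaging import detect_dual_view, detect_spots, extract_traces, register_views
from smfret.simulate import SimulationConfig, simulate_movie
from smfret.types import RegistrationError, Spot


def render_spot(shape, x, y, sigma, flux, background=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + (flux / (2 * np.pi * sigma**2)) * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


def movie_config(n_molecules=8, noise_sd=0.0, seed=4, record_s=4.0):
    return SimulationConfig(
        n_molecules=n_molecules,
        state_means=(0.5,),
        state_widths=(0.05,),
        state_weights=(1.0,),
        acceptor_bleach_mean_s=3.0,
        donor_bleach_mean_s=3.0,
        noise_sd=noise_sd,
        background=20.0,
        record_s=record_s,
        seed=seed,
    )


class TestDetect:
    def test_single_bright_spot_found_subpixel(self):
        frame = render_spot((48, 48), x=20.3, y=31.7, sigma=1.2, flux=5000.0)
        rng = np.random.default_rng(1)
        frame = frame + rng.normal(0, 55.0, frame.shape)  # amplitude ~10x noise
        spots = detect_spots(frame, threshold_sd=5.0, psf_sigma_px=1.2)
        assert len(spots) == 1
        assert abs(spots[0].x - 20.3) < 0.5
        assert abs(spots[0].y - 31.7) < 0.5

    def test_pure_noise_false_positive_rate(self):
        """< 0.01 detections per frame over 100 seeded noise frames at 5 sigma."""
        rng = np.random.default_rng(7)
        detections = 0
        for _ in range(100):
            frame = rng.normal(100.0, 10.0, (64, 64))
            detections += len(detect_spots(frame, threshold_sd=5.0, psf_sigma_px=1.2))
        assert detections / 100 < 0.01

    def test_blank_frame_empty(self):
        assert detect_spots(np.full((32, 32), 7.0)) == []

    def test_non_2d_input_raises(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((3, 4, 5)))

    def test_counts_match_truth_on_clean_movie(self):
        cfg = movie_config(n_molecules=8)
        stack, truth = simulate_movie(cfg, image_shape=(72, 144), psf_sigma_px=1.2)
        donor_spots, acceptor_spots = detect_dual_view(stack[0], 5.0, 1.2)
        assert len(donor_spots) == truth.n_molecules
        assert len(acceptor_spots) == truth.n_molecules


class TestRegistration:
    @staticmethod
    def _spots(points, view):
        return [Spot(float(x), float(y), 1.0, view) for x, y in points]

    def test_pure_half_frame_offset_is_identity(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(10, 50, (8, 2))
        donor = self._spots(pts, "donor")
        acceptor = self._spots(pts + [64.0, 0.0], "acceptor")
        reg = register_views(donor, acceptor, nominal_offset_px=(64.0, 0.0))
        np.testing.assert_allclose(reg.matrix, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(reg.offset, [64.0, 0.0], atol=1e-9)
        assert reg.residual_rms_px < 1e-9

    def test_extra_translation_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(10, 50, (10, 2))
        donor = self._spots(pts, "donor")
        acceptor = self._spots(pts + [64.0 + 3.2, -1.7], "acceptor")
        reg = register_views(donor, acceptor, nominal_offset_px=(64.0, 0.0))
        np.testing.assert_allclose(reg.offset, [67.2, -1.7], atol=0.1)

    def test_robust_to_outlier_pairs(self):
        """20% of acceptor spots displaced; translation still within 0.2 px."""
        rng = np.random.default_rng(4)
        pts = rng.uniform(10, 110, (20, 2))
        shifted = pts + [128.0 + 3.2, -1.7]
        shifted[:4] += rng.uniform(2.5, 3.8, (4, 2))  # outliers
        reg = register_views(
            self._spots(pts, "donor"),
            self._spots(shifted, "acceptor"),
            max_pair_dist_px=6.0,
            nominal_offset_px=(128.0, 0.0),
        )
        np.testing.assert_allclose(reg.offset, [131.2, -1.7], atol=0.2)
        np.testing.assert_allclose(reg.matrix, np.eye(2), atol=0.02)

    def test_too_few_spots_raises(self):
        with pytest.raises(RegistrationError):
            register_views(self._spots([(1, 1)], "donor"), self._spots([(2, 2)], "acceptor"))

    def test_noise_free_movie_registration_subpixel(self):
        cfg = movie_config(n_molecules=8)
        stack, truth = simulate_movie(
            cfg, image_shape=(72, 144), psf_sigma_px=1.2, view_offset=(2.0, -1.0)
        )
        donor_spots, acceptor_spots = detect_dual_view(stack[0], 5.0, 1.2)
        reg = register_views(donor_spots, acceptor_spots, nominal_offset_px=(72.0, 0.0))
        assert reg.residual_rms_px < 0.05
        np.testing.assert_allclose(reg.offset, [74.0, -1.0], atol=0.05)
        np.testing.assert_allclose(reg.matrix, np.eye(2), atol=1e-3)


class TestExtraction:
    def test_no_spots_gives_empty(self):
        from smfret.types import ViewRegistration

        reg = ViewRegistration(np.eye(2), np.array([16.0, 0.0]), 0.0, 3)
        assert extract_traces(np.full((5, 32, 32), 10.0), reg, []) == []

    def test_noise_free_round_trip_within_two_percent(self):
        """simulate_movie -> detect -> register -> extract recovers the traces."""
        cfg = movie_config(n_molecules=6)
        stack, truth = simulate_movie(cfg, image_shape=(72, 144), psf_sigma_px=1.2)
        donor_spots, acceptor_spots = detect_dual_view(stack[0], 5.0, 1.2)
        reg = register_views(donor_spots, acceptor_spots, nominal_offset_px=(72.0, 0.0))
        traces = extract_traces(stack, reg, donor_spots, psf_sigma_px=1.2)
        assert len(traces) == truth.n_molecules

        matched = self._match(truth, donor_spots)
        for ti, mi in matched:
            b = truth.acceptor_bleach_frame[mi]
            end = stack.shape[0] if b is None else b
            expected_d = 1000.0 * (1 - truth.efficiencies[mi][:end])
            expected_a = 1000.0 * truth.efficiencies[mi][:end]
            got = traces[ti]
            np.testing.assert_allclose(got.donor[:end], expected_d, rtol=0.02)
            np.testing.assert_allclose(got.acceptor[:end], expected_a, rtol=0.02)

    def test_acceptor_bleach_visible_in_extracted_trace(self):
        cfg = movie_config(n_molecules=4, seed=8)
        stack, truth = simulate_movie(cfg, image_shape=(72, 144), psf_sigma_px=1.2)
        donor_spots, acceptor_spots = detect_dual_view(stack[0], 5.0, 1.2)
        reg = register_views(donor_spots, acceptor_spots, nominal_offset_px=(72.0, 0.0))
        traces = extract_traces(stack, reg, donor_spots, psf_sigma_px=1.2)
        for ti, mi in self._match(truth, donor_spots):
            b = truth.acceptor_bleach_frame[mi]
            if b is None or b < 2 or b > stack.shape[0] - 2:
                continue
            tr = traces[ti]
            assert tr.acceptor[b] < 0.2 * tr.acceptor[: b].mean()
            assert tr.donor[b] > tr.donor[:b].mean()

    def test_noisy_forward_inverse_consistency(self):
        """At spot SNR >= 10 the recovered pre-bleach intensities err < 5%."""
        cfg = movie_config(n_molecules=6, noise_sd=2.5, seed=12)
        stack, truth = simulate_movie(cfg, image_shape=(72, 144), psf_sigma_px=1.2)
        n_det = 5
        image = stack[:n_det].mean(axis=0)
        donor_spots, acceptor_spots = detect_dual_view(image, 5.0, 1.2)
        reg = register_views(donor_spots, acceptor_spots, nominal_offset_px=(72.0, 0.0))
        traces = extract_traces(stack, reg, donor_spots, psf_sigma_px=1.2)
        rel_errors = []
        for ti, mi in self._match(truth, donor_spots):
            b = truth.acceptor_bleach_frame[mi]
            end = stack.shape[0] if b is None else b
            if end < 3:
                continue
            expected = 1000.0 * np.ones(end)  # total intensity is conserved pre-bleach
            got = traces[ti].donor[:end] + traces[ti].acceptor[:end]
            rel_errors.append(np.abs(got - expected) / expected)
        assert np.mean(np.concatenate(rel_errors)) < 0.05

    @staticmethod
    def _match(truth, donor_spots):
        """(trace index, truth molecule index) pairs by nearest spot position."""
        pos = np.asarray(truth.spot_positions)
        out = []
        for ti, s in enumerate(donor_spots):
            d = np.hypot(pos[:, 0] - s.x, pos[:, 1] - s.y)
            out.append((ti, int(np.argmin(d))))
        return out
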
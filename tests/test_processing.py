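"""Smoothing, change-point detection, FRET-pair selection, gamma, efficiency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfret.processing import (
    compute_efficiency,
    detect_bleach_steps,
    estimate_gamma,
    moving_average,
    select_fret_pairs,
    smooth_trace,
)
from smfret.types import AnalysisError, IntensityTrace, TraceSelection


def brute_force_moving_average(x, window):
    """Oracle: explicit per-frame windowed mean with the documented alignment."""
    n = len(x)
    fwd = window // 2
    back = window - 1 - fwd
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - back)
        hi = min(n, i + fwd + 1)
        out[i] = np.mean(x[lo:hi])
    return out


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        tr = IntensityTrace(0, 10.0, np.full(50, 100.0), np.full(50, 100.0))
        out = smooth_trace(tr, window_s=1.7)
        np.testing.assert_array_equal(out.donor, tr.donor)

    def test_one_second_window_is_ten_frames_at_10fps(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 5, 200)
        tr = IntensityTrace(0, 10.0, x, x)
        out = smooth_trace(tr, window_s=1.0)
        np.testing.assert_allclose(out.donor, brute_force_moving_average(x, 10), atol=1e-12)

    def test_impulse_spreads_over_the_centered_window(self):
        x = np.zeros(100)
        x[50] = 1.0
        out = moving_average(x, 10)
        nz = np.flatnonzero(out)
        np.testing.assert_array_equal(nz, np.arange(45, 55))
        np.testing.assert_allclose(out[nz], 0.1)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=200),
        window=st.integers(1, 25),
    )
    def test_matches_brute_force_oracle(self, data, window):
        x = np.asarray(data)
        np.testing.assert_allclose(
            moving_average(x, window), brute_force_moving_average(x, window), atol=1e-12
        )


class TestStepDetection:
    def test_noise_free_single_step_exact(self):
        x = np.concatenate([np.full(50, 100.0), np.zeros(50)])
        events = detect_bleach_steps(x, channel="acceptor")
        assert len(events) == 1
        assert events[0].frame == 50
        assert events[0].delta == pytest.approx(-100.0)

    def test_noise_free_two_steps_at_true_frames(self):
        x = np.concatenate([np.full(40, 100.0), np.full(30, 60.0), np.zeros(30)])
        events = detect_bleach_steps(x)
        assert [e.frame for e in events] == [40, 70]
        assert events[0].delta == pytest.approx(-40.0)
        assert events[1].delta == pytest.approx(-60.0)

    def test_too_short_trace_skipped(self):
        assert detect_bleach_steps(np.array([5.0, 1.0, 0.0])) == []

    def test_noisy_step_localized_within_two_frames(self):
        """step/noise = 5: detected change point within +/-2 frames in >= 95% of trials."""
        rng = np.random.default_rng(123)
        hits = 0
        n_trials = 500
        for _ in range(n_trials):
            x = np.concatenate([np.full(60, 100.0), np.zeros(40)])
            x += rng.normal(0, 20.0, x.size)
            events = detect_bleach_steps(x, max_steps=1)
            if events and abs(events[0].frame - 60) <= 2:
                hits += 1
        assert hits / n_trials >= 0.95

    def test_null_trace_rarely_yields_a_step(self):
        """Pure-noise traces produce an accepted step in < 5% of seeded trials."""
        rng = np.random.default_rng(99)
        false_pos = 0
        n_trials = 200
        for _ in range(n_trials):
            x = rng.normal(100.0, 10.0, 100)
            if detect_bleach_steps(x, max_steps=1, accept_k=3.0):
                false_pos += 1
        assert false_pos / n_trials < 0.05


def _fret_pair_trace(mol=0, n=100, b_a=50, level=100.0, noise=0.0, seed=0):
    """Textbook FRET pair: acceptor bleaches at b_a, donor recovers, no donor bleach."""
    rng = np.random.default_rng(seed)
    acceptor = np.where(np.arange(n) < b_a, 0.7 * level, 0.0)
    donor = np.where(np.arange(n) < b_a, 0.3 * level, level)
    if noise:
        acceptor = acceptor + rng.normal(0, noise, n)
        donor = donor + rng.normal(0, noise, n)
    return IntensityTrace(mol, 10.0, donor, acceptor)


class TestSelection:
    def test_generated_fret_pairs_accepted(self, factin_dataset):
        selections = factin_dataset["selections"]
        accepted = sum(s.accepted for s in selections)
        assert accepted / len(selections) > 0.8

    def test_textbook_pair_accepted(self):
        sel, _ = select_fret_pairs([_fret_pair_trace()])
        assert sel[0].accepted
        assert sel[0].acceptor_bleach_frame == 50

    def test_donor_only_rejected(self):
        n = 100
        donor = np.concatenate([np.full(60, 100.0), np.zeros(40)])
        acceptor = np.zeros(n) + 1e-3 * np.sin(np.arange(n))  # background wiggle
        sel, _ = select_fret_pairs([IntensityTrace(0, 10.0, donor, acceptor)])
        assert not sel[0].accepted
        assert sel[0].reason == "no_acceptor_bleach"

    def test_correlated_drop_without_recovery_rejected(self):
        """Both channels stepping down together is not FRET (no donor recovery)."""
        donor = np.concatenate([np.full(40, 100.0), np.full(30, 60.0), np.zeros(30)])
        acceptor = np.concatenate([np.full(40, 80.0), np.full(30, 40.0), np.zeros(30)])
        sel, _ = select_fret_pairs([IntensityTrace(0, 10.0, donor, acceptor)])
        assert not sel[0].accepted
        assert sel[0].reason == "no_donor_recovery"

    def test_state_transition_is_not_mistaken_for_bleach(self):
        """A partial anti-correlated step (conformational transition) must not
        disqualify the molecule."""
        n, t, b = 120, 40, 90
        frames = np.arange(n)
        acceptor = np.select([frames < t, frames < b], [75.0, 54.0], default=0.0)
        donor = np.select([frames < t, frames < b], [25.0, 46.0], default=100.0)
        sel, _ = select_fret_pairs([IntensityTrace(0, 10.0, donor, acceptor)])
        assert sel[0].accepted
        assert sel[0].acceptor_bleach_frame == b


class TestGamma:
    def _selection(self, mol=0, b=100):
        return [TraceSelection(mol, True, "ok", acceptor_bleach_frame=b)]

    def test_unit_gamma_from_symmetric_recovery(self):
        n, b = 200, 100
        acceptor = np.where(np.arange(n) < b, 100.0, 0.0)
        donor = np.where(np.arange(n) < b, 50.0, 150.0)
        est = estimate_gamma([IntensityTrace(0, 10.0, donor, acceptor)], self._selection())
        assert est.gamma == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        """dI_a = -80, dI_d = +50 -> gamma = 1.6."""
        n, b = 200, 100
        acceptor = np.where(np.arange(n) < b, 80.0, 0.0)
        donor = np.where(np.arange(n) < b, 50.0, 100.0)
        est = estimate_gamma([IntensityTrace(0, 10.0, donor, acceptor)], self._selection())
        assert est.gamma == pytest.approx(1.6)

    def test_scale_invariance(self, factin_dataset):
        traces = factin_dataset["traces"][:60]
        selections = [s for s in factin_dataset["selections"] if s.molecule_id < 60]
        base = estimate_gamma(traces, selections).gamma
        scaled = [
            IntensityTrace(tr.molecule_id, tr.frame_rate, 7.3 * tr.donor, 7.3 * tr.acceptor)
            for tr in traces
        ]
        assert estimate_gamma(scaled, selections).gamma == pytest.approx(base, rel=1e-12)

    def test_recovers_true_gamma_within_five_percent(self):
        """200 molecules, gamma_true = 1.3, 5% channel noise -> median within 5%."""
        from smfret.simulate import SimulationConfig, simulate_traces

        cfg = SimulationConfig(
            n_molecules=200,
            state_means=(0.54, 0.75),
            state_widths=(0.08, 0.08),
            state_weights=(0.5, 0.5),
            gamma_true=1.3,
            noise_sd=50.0,  # 5% of total_intensity=1000
            seed=17,
            record_s=40.0,
        )
        traces, _ = simulate_traces(cfg)
        selections, _ = select_fret_pairs(traces)
        est = estimate_gamma(traces, selections)
        assert est.gamma == pytest.approx(1.3, rel=0.05)

    def test_no_usable_molecules_is_an_error(self):
        tr = _fret_pair_trace()
        with pytest.raises(AnalysisError):
            estimate_gamma([tr], [TraceSelection(0, False, "no_acceptor_bleach")])


class TestEfficiency:
    def test_hand_values(self):
        tr = IntensityTrace(0, 10.0, donor=np.full(20, 20.0), acceptor=np.full(20, 80.0))
        ft = compute_efficiency(tr, gamma=1.0, smooth_window_s=None)
        np.testing.assert_allclose(ft.valid_efficiencies, 0.8)
        tr2 = IntensityTrace(0, 10.0, donor=np.full(20, 40.0), acceptor=np.full(20, 60.0))
        ft2 = compute_efficiency(tr2, gamma=1.5, smooth_window_s=None)
        np.testing.assert_allclose(ft2.valid_efficiencies, 0.5)

    def test_efficiency_clipped_and_masked(self):
        donor = np.array([10.0, -20.0, 5.0, 0.0, 10.0])
        acceptor = np.array([-5.0, 10.0, -10.0, 0.0, 90.0])
        ft = compute_efficiency(IntensityTrace(0, 10.0, donor, acceptor), 1.0, smooth_window_s=None)
        assert np.all(ft.valid_efficiencies >= 0.0)
        assert np.all(ft.valid_efficiencies <= 1.0)
        assert not ft.valid_mask[3]  # zero denominator frame is invalid
        assert ft.clipped_mask[0]  # negative ratio was clipped

    def test_valid_frames_precede_bleach(self):
        tr = _fret_pair_trace()
        ft = compute_efficiency(tr, 1.0, bleach_frame=50)
        assert ft.n_valid == 50
        assert not ft.valid_mask[50:].any()
        assert np.isnan(ft.efficiency[50:]).all()

    def test_all_efficiencies_in_unit_interval(self, factin_dataset):
        for ft in factin_dataset["fret"]:
            e = ft.valid_efficiencies
            assert np.all((e >= 0.0) & (e <= 1.0))

    def test_no_valid_frames_warns_and_returns_empty(self):
        tr = _fret_pair_trace()
        with pytest.warns(UserWarning):
            ft = compute_efficiency(tr, 1.0, bleach_frame=0)
        assert ft.n_valid == 0
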
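"""Shared fixtures: session-scoped synthetic datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from smfret.mixture import pool_efficiencies
from smfret.processing import compute_efficiency, select_fret_pairs
from smfret.simulate import SimulationConfig, load_preset, simulate_traces


def truth_efficiencies(traces, truth, smooth_window_s=1.0):
    """Efficiency traces computed with the generator's true gamma and bleach frames."""
    out = []
    for tr, b in zip(traces, truth.acceptor_bleach_frame):
        end = len(tr) if b is None else b
        if end < 1:
            continue
        ft = compute_efficiency(tr, truth.gamma_true, bleach_frame=end, smooth_window_s=smooth_window_s)
        if ft.n_valid > 0:
            out.append(ft)
    return out


@pytest.fixture(scope="session")
def factin_dataset():
    """One factin-preset realization: traces, truth, and fully processed efficiencies."""
    cfg = load_preset("factin").config.model_copy(update={"seed": 11})
    traces, truth = simulate_traces(cfg)
    selections, _ = select_fret_pairs(traces)
    by_id = {tr.molecule_id: tr for tr in traces}
    fret, fret_raw = [], []
    for s in selections:
        if not s.accepted:
            continue
        smooth = compute_efficiency(by_id[s.molecule_id], cfg.gamma_true, s.acceptor_bleach_frame, 1.0)
        if smooth.n_valid > 0:
            fret.append(smooth)
            fret_raw.append(
                compute_efficiency(by_id[s.molecule_id], cfg.gamma_true, s.acceptor_bleach_frame, None)
            )
    sample, _ = pool_efficiencies(fret)
    sample_raw, _ = pool_efficiencies(fret_raw)
    return {
        "config": cfg,
        "traces": traces,
        "truth": truth,
        "selections": selections,
        "fret": fret,
        "fret_raw": fret_raw,
        "sample": sample,
        "sample_raw": sample_raw,
    }


@pytest.fixture
def tiny_config():
    """Small, fast simulation config for structural tests."""
    return SimulationConfig(
        n_molecules=20,
        state_means=(0.4, 0.8),
        state_widths=(0.05, 0.05),
        state_weights=(0.5, 0.5),
        record_s=20.0,
        noise_sd=20.0,
        seed=5,
    )
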
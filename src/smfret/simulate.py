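"""Forward model for single-molecule FRET recordings.

Generates two-channel (donor/acceptor) intensity traces — and optionally
dual-view movies — with the statistical structure the analysis layer
assumes: a hidden continuous-time Markov state process with long dwell
times, per-frame efficiency jitter drawn from each state's Gaussian,
anti-correlated channel intensities consistent with a detection-correction
factor gamma, acceptor-then-donor photobleaching that truncates the usable
record, and additive camera noise.  Every draw is tied to the config seed so
identical configs give bit-identical output, and the hidden truth is
returned alongside for estimator-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .types import CapacityError, IntensityTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConditionPreset",
    "PRESETS",
    "load_preset",
    "simulate_traces",
    "simulate_movie",
    "sample_state_path",
]


class SimulationConfig(BaseModel):
    """Full generative description of a synthetic FRET dataset.

    Defaults mirror the experimental regime the analysis is designed for:
    10 fps acquisition, state dwell times of ~150 s, and acceptor
    photobleaching after ~5 s so that most records end long before a state
    transition occurs.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    frame_rate: float = Field(10.0, gt=0, description="frames per second")
    n_molecules: int = Field(100, ge=0)
    state_means: tuple[float, ...] = (0.54, 0.75)
    state_widths: tuple[float, ...] = (0.08, 0.08)
    state_weights: tuple[float, ...] = (0.5, 0.5)
    dwell_mean_s: float = Field(150.0, gt=0, description="mean state dwell time, seconds")
    total_intensity: float = Field(1000.0, gt=0, description="mean I_a + gamma*I_d per frame, a.u.")
    gamma_true: float = Field(1.0, gt=0)
    acceptor_bleach_mean_s: float = Field(5.0, gt=0)
    donor_bleach_mean_s: float = Field(
        5.0, gt=0, description="mean extra survival of the donor after the acceptor bleach"
    )
    noise_sd: float = Field(0.0, ge=0, description="additive Gaussian noise sd per channel")
    background: float = Field(0.0, ge=0, description="additive offset per channel")
    record_s: float = Field(60.0, gt=0, description="record length, seconds")
    seed: int = 0

    @model_validator(mode="after")
    def _check_states(self) -> "SimulationConfig":
        means = np.asarray(self.state_means, dtype=float)
        widths = np.asarray(self.state_widths, dtype=float)
        weights = np.asarray(self.state_weights, dtype=float)
        if not (len(means) == len(widths) == len(weights)):
            raise ValueError("state_means, state_widths and state_weights must have equal length")
        if means.size == 0:
            raise ValueError("state_means must not be empty")
        if np.any(means <= 0) or np.any(means >= 1):
            raise ValueError("state_means must lie in the open interval (0, 1)")
        if np.any(np.diff(means) <= 0):
            raise ValueError("state_means must be strictly increasing")
        if np.any(widths <= 0):
            raise ValueError("state_widths must be strictly positive")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("state_weights must be non-negative and sum to 1 within 1e-9")
        return self

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    @property
    def n_frames(self) -> int:
        return int(round(self.record_s * self.frame_rate))


@dataclass
class GroundTruth:
    """Hidden truth of a simulated dataset, for estimator-recovery tests."""

    frame_rate: float
    gamma_true: float
    states: list  # per molecule: int array, hidden state index per frame
    efficiencies: list  # per molecule: float array, per-frame E actually drawn
    acceptor_bleach_frame: list  # int or None (never bleached in record)
    donor_bleach_frame: list  # int or None
    transition_counts: list  # hidden transitions within the observable span
    spot_positions: Optional[list] = None  # (x, y) donor-view positions, movies only
    view_offset: Optional[tuple] = None  # extra (dx, dy) of acceptor view, movies only
    psf_sigma_px: Optional[float] = None

    @property
    def n_molecules(self) -> int:
        return len(self.states)

    def observable_frames(self, i: int) -> int:
        """Number of frames before the acceptor bleach for molecule ``i``."""
        b = self.acceptor_bleach_frame[i]
        return len(self.states[i]) if b is None else int(b)

    def mean_observable_span_s(self) -> float:
        spans = [self.observable_frames(i) for i in range(self.n_molecules)]
        return float(np.mean(spans)) / self.frame_rate

    def to_dict(self) -> dict:
        d = {
            "frame_rate": self.frame_rate,
            "gamma_true": self.gamma_true,
            "states": [np.asarray(s).tolist() for s in self.states],
            "efficiencies": [np.asarray(e).tolist() for e in self.efficiencies],
            "acceptor_bleach_frame": list(self.acceptor_bleach_frame),
            "donor_bleach_frame": list(self.donor_bleach_frame),
            "transition_counts": list(self.transition_counts),
        }
        if self.spot_positions is not None:
            d["spot_positions"] = [list(map(float, p)) for p in self.spot_positions]
        if self.view_offset is not None:
            d["view_offset"] = list(map(float, self.view_offset))
        if self.psf_sigma_px is not None:
            d["psf_sigma_px"] = float(self.psf_sigma_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            frame_rate=d["frame_rate"],
            gamma_true=d["gamma_true"],
            states=[np.asarray(s, dtype=int) for s in d["states"]],
            efficiencies=[np.asarray(e, dtype=float) for e in d["efficiencies"]],
            acceptor_bleach_frame=d["acceptor_bleach_frame"],
            donor_bleach_frame=d["donor_bleach_frame"],
            transition_counts=d["transition_counts"],
            spot_positions=[tuple(p) for p in d["spot_positions"]] if "spot_positions" in d else None,
            view_offset=tuple(d["view_offset"]) if "view_offset" in d else None,
            psf_sigma_px=d.get("psf_sigma_px"),
        )


@dataclass
class ConditionPreset:
    """Named experimental condition with its generative parameters."""

    name: str
    config: SimulationConfig
    description: str = ""


def _preset_config(**overrides) -> SimulationConfig:
    base = dict(
        frame_rate=10.0,
        dwell_mean_s=150.0,
        total_intensity=1000.0,
        gamma_true=1.0,
        acceptor_bleach_mean_s=5.0,
        donor_bleach_mean_s=5.0,
        noise_sd=30.0,
        background=0.0,
        record_s=60.0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# Emission peaks follow the three conformational states resolved in the
# pooled efficiency histograms: f = 0.37, fg = 0.54, g = 0.75.  Weights are
# set so the pooled mean efficiency matches the printed condition averages
# (G-actin low salt: mean E = 0.70; F-actin: mean E ~ 0.51), with the
# high-salt G-actin preset fg-enriched relative to low salt.
PRESETS: dict = {
    "gactin_low_salt": ConditionPreset(
        name="gactin_low_salt",
        config=_preset_config(
            n_molecules=312,
            state_means=(0.54, 0.75),
            state_widths=(0.08, 0.08),
            state_weights=(0.24, 0.76),
        ),
        description="monomeric actin, low ionic strength; g-state dominant, mean E = 0.70",
    ),
    "gactin_high_salt": ConditionPreset(
        name="gactin_high_salt",
        config=_preset_config(
            n_molecules=109,
            state_means=(0.54, 0.75),
            state_widths=(0.08, 0.08),
            state_weights=(0.45, 0.55),
        ),
        description="monomeric actin, 150 mM KCl; fg-state enriched",
    ),
    "factin": ConditionPreset(
        name="factin",
        config=_preset_config(
            n_molecules=374,
            state_means=(0.37, 0.54, 0.75),
            state_widths=(0.08, 0.08, 0.08),
            state_weights=(0.45, 0.35, 0.20),
        ),
        description="filamentous actin; f state appears, mean E ~ 0.51",
    ),
}


def load_preset(name: str) -> ConditionPreset:
    """Return a named condition preset (a fresh copy, safe to mutate)."""
    try:
        preset = PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; valid names: {valid}") from None
    return ConditionPreset(
        name=preset.name,
        config=preset.config.model_copy(deep=True),
        description=preset.description,
    )


def sample_state_path(
    rng: np.random.Generator,
    n_states: int,
    weights: Sequence[float],
    dwell_mean_s: float,
    duration_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one continuous-time Markov path over ``[0, duration_s]``.

    Dwells are exponential with mean ``dwell_mean_s``; on leaving a state the
    chain jumps uniformly among the other states.  Returns ``(times, states)``
    where ``times[j]`` is the entry time of ``states[j]`` (``times[0] == 0``).
    """
    weights = np.asarray(weights, dtype=float)
    times = [0.0]
    states = [int(rng.choice(n_states, p=weights))]
    t = float(rng.exponential(dwell_mean_s))
    while t < duration_s and n_states > 1:
        others = [s for s in range(n_states) if s != states[-1]]
        states.append(int(rng.choice(others)))
        times.append(t)
        t += float(rng.exponential(dwell_mean_s))
    return np.asarray(times), np.asarray(states, dtype=int)


def _states_at_frames(times: np.ndarray, states: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(times, frame_times, side="right") - 1
    return states[idx]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_traces(config: SimulationConfig) -> tuple[list[IntensityTrace], GroundTruth]:
    """Generate per-molecule two-channel traces plus their hidden truth.

    Channel construction guarantees the exact inverse relation of the
    efficiency formula: with per-frame efficiency draw ``E`` and summed
    intensity ``T``, the acceptor gets ``T*E`` and the donor
    ``T*(1-E)/gamma_true``, so ``I_a / (I_a + gamma_true*I_d) == E`` in the
    noise-free limit.  After the acceptor bleach the acceptor falls to
    background and the donor recovers to the full level ``T/gamma_true``;
    after the donor bleach both channels sit at background.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    frame_times = np.arange(n_frames) / config.frame_rate

    traces: list[IntensityTrace] = []
    gt_states, gt_eff = [], []
    gt_ab, gt_db, gt_tc = [], [], []

    for mol in range(config.n_molecules):
        times, path = sample_state_path(
            rng, config.n_states, config.state_weights, config.dwell_mean_s, config.record_s
        )
        states = _states_at_frames(times, path, frame_times)

        # Acceptor bleaches first; the donor survives an extra exponential time.
        t_a = rng.exponential(config.acceptor_bleach_mean_s)
        t_d = t_a + rng.exponential(config.donor_bleach_mean_s)
        b_a = int(np.ceil(t_a * config.frame_rate))
        b_d = int(np.ceil(t_d * config.frame_rate))

        eff = np.empty(n_frames)
        for s in range(config.n_states):
            m = states == s
            if m.any():
                eff[m] = _truncated_normal(
                    rng, config.state_means[s], config.state_widths[s], int(m.sum())
                )

        T = config.total_intensity
        acceptor = T * eff
        donor = T * (1.0 - eff) / config.gamma_true
        if b_a < n_frames:
            acceptor[b_a:] = 0.0
            donor[b_a:] = T / config.gamma_true
        if b_d < n_frames:
            donor[b_d:] = 0.0

        donor = donor + config.background
        acceptor = acceptor + config.background
        if config.noise_sd > 0:
            donor = donor + rng.normal(0.0, config.noise_sd, n_frames)
            acceptor = acceptor + rng.normal(0.0, config.noise_sd, n_frames)

        n_obs = min(b_a, n_frames)
        transitions = int(np.count_nonzero(np.diff(states[:n_obs]))) if n_obs > 1 else 0

        traces.append(IntensityTrace(mol, config.frame_rate, donor, acceptor))
        gt_states.append(states)
        gt_eff.append(eff)
        gt_ab.append(b_a if b_a < n_frames else None)
        gt_db.append(b_d if b_d < n_frames else None)
        gt_tc.append(transitions)

    truth = GroundTruth(
        frame_rate=config.frame_rate,
        gamma_true=config.gamma_true,
        states=gt_states,
        efficiencies=gt_eff,
        acceptor_bleach_frame=gt_ab,
        donor_bleach_frame=gt_db,
        transition_counts=gt_tc,
    )
    return traces, truth


def _place_spots(
    rng: np.random.Generator,
    n: int,
    half_width: int,
    height: int,
    psf_sigma_px: float,
    margin: float,
    min_sep: float,
    max_tries: int = 20000,
) -> np.ndarray:
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < n:
        if tries >= max_tries:
            raise CapacityError(
                f"could not place {n} spots with separation {min_sep:.1f}px "
                f"in a {half_width}x{height} half-view"
            )
        tries += 1
        x = rng.uniform(margin, half_width - 1 - margin)
        y = rng.uniform(margin, height - 1 - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in positions):
            positions.append((x, y))
    return np.asarray(positions)


def simulate_movie(
    config: SimulationConfig,
    image_shape: tuple[int, int] = (64, 128),
    psf_sigma_px: float = 1.2,
    view_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, GroundTruth]:
    """Render the simulated molecules as a dual-view image stack.

    The frame is split at the horizontal midline: left half donor view, right
    half acceptor view.  Each molecule is a 2-D Gaussian spot of width
    ``psf_sigma_px`` whose integrated intensity per frame equals the trace
    value; the acceptor spot sits at the donor position translated by the
    half-frame width plus ``view_offset`` (recorded in the truth).  Spots are
    placed at least ``4*psf_sigma_px`` apart with a margin wide enough for
    aperture photometry.
    """
    height, width = image_shape
    if width % 2 != 0:
        raise ValueError("image width must be even (two side-by-side views)")
    half = width // 2

    # Noise enters at the pixel level for movies; the rendered spot fluxes
    # are the noise-free channel signals.
    trace_cfg = config.model_copy(update={"noise_sd": 0.0, "background": 0.0})
    traces, truth = simulate_traces(trace_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5B07]))

    margin = 7.0 * psf_sigma_px  # aperture (3 sigma) + background annulus (6 sigma) clearance
    min_sep = 4.0 * psf_sigma_px
    if 2 * margin >= min(half - 1, height - 1):
        raise CapacityError("image too small for the requested PSF width")
    positions = (
        _place_spots(rng, config.n_molecules, half, height, psf_sigma_px, margin, min_sep)
        if config.n_molecules > 0
        else np.empty((0, 2))
    )
    dx, dy = view_offset
    acc_positions = positions + np.asarray([half + dx, dy]) if len(positions) else positions

    n_frames = config.n_frames
    stack = np.full((n_frames, height, width), float(config.background))
    norm = 2.0 * np.pi * psf_sigma_px**2
    win = int(np.ceil(5 * psf_sigma_px))
    yy, xx = np.mgrid[-win : win + 1, -win : win + 1]

    def render(frame: np.ndarray, x: float, y: float, flux: float) -> None:
        cx, cy = int(round(x)), int(round(y))
        gx = xx + cx - x
        gy = yy + cy - y
        patch = (flux / norm) * np.exp(-(gx**2 + gy**2) / (2 * psf_sigma_px**2))
        frame[cy - win : cy + win + 1, cx - win : cx + win + 1] += patch

    for i, tr in enumerate(traces):
        for k in range(n_frames):
            render(stack[k], positions[i, 0], positions[i, 1], tr.donor[k])
            render(stack[k], acc_positions[i, 0], acc_positions[i, 1], tr.acceptor[k])

    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, stack.shape)

    truth.spot_positions = [tuple(p) for p in positions]
    truth.view_offset = (float(dx), float(dy))
    truth.psf_sigma_px = float(psf_sigma_px)
    return stack, truth
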
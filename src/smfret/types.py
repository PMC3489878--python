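"""Core containers shared across the pipeline stages.

Conventions used throughout the package:

* frames are 0-based; frame ``k`` of a trace acquired at ``frame_rate``
  frames per second is observed at time ``k / frame_rate`` seconds;
* intensities are background-subtracted arbitrary units (camera counts);
* pixel coordinates are 0-based with pixel centers at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "IntensityTrace",
    "Spot",
    "ViewRegistration",
    "BleachEvent",
    "TraceSelection",
    "GammaEstimate",
    "FretTrace",
    "StateModel",
    "StateAssignment",
    "KineticsEstimate",
    "FoersterParams",
    "DistanceResult",
    "CapacityError",
    "RegistrationError",
    "FitError",
    "AnalysisError",
]


class AnalysisError(RuntimeError):
    """A pipeline stage could not produce a result from its input."""


class CapacityError(ValueError):
    """Requested more spots than the frame geometry can hold."""


class RegistrationError(AnalysisError):
    """Too few point pairs survived to fit a dual-view registration."""


class FitError(AnalysisError):
    """Every mixture-fit restart collapsed onto a degenerate component."""


@dataclass
class IntensityTrace:
    """Two-channel intensity time series for one molecule."""

    molecule_id: int
    frame_rate: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D arrays of equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class Spot:
    """A detected diffraction-limited spot, sub-pixel position in full-frame coordinates."""

    x: float
    y: float
    amplitude: float
    view: str  # "donor" | "acceptor"


@dataclass
class ViewRegistration:
    """Affine map from donor-view to acceptor-view coordinates.

    ``matrix`` is a 2x2 linear part, ``offset`` a length-2 translation, so a
    donor position ``p`` maps to ``matrix @ p + offset``.
    """

    matrix: np.ndarray
    offset: np.ndarray
    residual_rms_px: float
    n_pairs: int

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ np.asarray(self.matrix).T + np.asarray(self.offset)


@dataclass
class BleachEvent:
    """A step change detected in one channel of a raw trace.

    ``frame`` is the first frame of the post-step level; ``delta`` is
    ``post_level - pre_level`` (negative for a bleach)."""

    channel: str
    frame: int
    pre_level: float
    post_level: float

    @property
    def delta(self) -> float:
        return self.post_level - self.pre_level


@dataclass
class TraceSelection:
    """Outcome of the FRET-pair acceptance test for one molecule."""

    molecule_id: int
    accepted: bool
    reason: str  # "ok" when accepted
    acceptor_bleach_frame: Optional[int] = None
    donor_bleach_frame: Optional[int] = None
    donor_recovery_frame: Optional[int] = None


@dataclass
class GammaEstimate:
    """Condition-level detection-correction factor gamma.

    ``gamma`` is the median of the per-molecule ratios ``|dI_a / dI_d|``
    measured across the acceptor photobleach step."""

    gamma: float
    per_molecule_values: np.ndarray
    n: int


@dataclass
class FretTrace:
    """Gamma-corrected efficiency time series for one molecule.

    ``efficiency`` has the same length as the source trace with NaN outside
    ``valid_mask``; valid frames precede the acceptor bleach. ``clipped_mask``
    marks valid frames where the raw ratio fell outside [0, 1] before
    clipping."""

    molecule_id: int
    frame_rate: float
    efficiency: np.ndarray
    valid_mask: np.ndarray
    gamma_used: float
    mean_efficiency: float
    clipped_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def valid_efficiencies(self) -> np.ndarray:
        return self.efficiency[self.valid_mask]

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))


# Highest-mean component first: g (compact, high FRET), fg (intermediate),
# f (filament-specific, low FRET).
STATE_LABELS_BY_DESCENDING_MEAN = ("g", "fg", "f")


def labels_for_k(k: int) -> list[str]:
    """State names for a K-component model, ordered by *ascending* mean."""
    if not 1 <= k <= len(STATE_LABELS_BY_DESCENDING_MEAN):
        raise ValueError(f"K must be in 1..{len(STATE_LABELS_BY_DESCENDING_MEAN)}")
    return list(STATE_LABELS_BY_DESCENDING_MEAN[:k][::-1])


@dataclass
class StateModel:
    """Gaussian mixture over FRET efficiency; components sorted by ascending mean."""

    K: int
    means: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    state_labels: list[str]
    log_likelihood: float
    n_samples: int
    selection_score: Optional[dict] = None  # {"bic": {K: value}} when chosen by select_k
    log_likelihood_path: Optional[np.ndarray] = None  # per-iteration ll of the winning restart

    @property
    def bic(self) -> float:
        n_params = 3 * self.K - 1
        return -2.0 * self.log_likelihood + n_params * np.log(self.n_samples)

    def to_dict(self) -> dict:
        out = {
            "K": int(self.K),
            "means": [float(m) for m in self.means],
            "widths": [float(s) for s in self.widths],
            "weights": [float(w) for w in self.weights],
            "state_labels": list(self.state_labels),
            "log_likelihood": float(self.log_likelihood),
            "n_samples": int(self.n_samples),
            "bic": float(self.bic),
        }
        if self.selection_score is not None:
            out["selection_score"] = {
                k: {str(kk): float(vv) for kk, vv in v.items()}
                for k, v in self.selection_score.items()
            }
        return out


@dataclass
class StateAssignment:
    """Per-frame state labels for a set of traces under a fitted StateModel."""

    molecule_ids: list[int]
    frame_labels: list[np.ndarray]  # component index per valid frame, ascending-mean order
    dominant_state: list[str]
    state_fractions: dict  # label -> frame-weighted frequency, sums to 1
    labels: list[str]  # model labels, ascending-mean order

    def label_sequences(self) -> list[np.ndarray]:
        lab = np.asarray(self.labels, dtype=object)
        return [lab[idx] for idx in self.frame_labels]


@dataclass
class KineticsEstimate:
    """Censored-fraction lifetime estimate.

    With observation spans much shorter than the dwell time, the fraction of
    molecules showing at least one transition approximates T_obs / tau, so
    tau = T_obs / fraction."""

    n_molecules: int
    n_with_transition: int
    transition_fraction: float
    mean_observation_s: float
    lifetime_s: float
    transition_rate_per_s: float
    fraction_ci: tuple
    lifetime_ci_s: tuple
    is_lower_bound: bool = False

    def to_dict(self) -> dict:
        return {
            "n_molecules": int(self.n_molecules),
            "n_with_transition": int(self.n_with_transition),
            "transition_fraction": float(self.transition_fraction),
            "mean_observation_s": float(self.mean_observation_s),
            "lifetime_s": float(self.lifetime_s),
            "transition_rate_per_s": float(self.transition_rate_per_s),
            "fraction_ci": [float(v) for v in self.fraction_ci],
            "lifetime_ci_s": [None if v is None else float(v) for v in self.lifetime_ci_s],
            "is_lower_bound": bool(self.is_lower_bound),
        }


@dataclass
class FoersterParams:
    """Forster radius R0 (nm) of the dye pair: the distance at which E = 0.5."""

    r0_nm: float = 5.1

    def __post_init__(self) -> None:
        if self.r0_nm <= 0:
            raise ValueError("r0_nm must be positive")


@dataclass
class DistanceResult:
    efficiency: float
    distance_nm: float
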
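"""Transition counting, censored-lifetime estimation and distance conversion.

Photobleaching limits each record to a few seconds, far shorter than the
conformational dwell times, so per-state dwell fitting is impossible.
Instead the dwell lifetime tau follows from censoring arithmetic: when
T_obs << tau, the probability that a record of length T_obs catches at
least one transition is ~ T_obs / tau, so tau = T_obs / fraction.  FRET
efficiencies convert to inter-dye distances through the Forster relation
r = R0 * (1/E - 1)^(1/6).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import DistanceResult, FoersterParams, KineticsEstimate, StateAssignment

__all__ = [
    "count_transitions",
    "estimate_lifetime",
    "efficiency_to_distance",
    "distance_from_efficiency",
    "distance_shift",
]


def _run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run values, run lengths) of a label sequence."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return labels, np.empty(0, dtype=int)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def count_transitions(
    assignment: StateAssignment | list[np.ndarray], min_dwell_frames: int = 10
) -> tuple[np.ndarray, int]:
    """Count state transitions per molecule, suppressing brief flicker.

    A label change counts as a transition only when both the preceding and
    the following runs last at least ``min_dwell_frames`` (default 10
    frames = 1 s at 10 fps), so single-frame misassignments near a
    component boundary do not register as conformational events.

    Returns ``(per-molecule counts, number of molecules with >= 1)``.
    """
    if min_dwell_frames < 1:
        raise ValueError("min_dwell_frames must be >= 1")
    sequences = (
        assignment.frame_labels if isinstance(assignment, StateAssignment) else assignment
    )
    counts = np.zeros(len(sequences), dtype=int)
    for i, seq in enumerate(sequences):
        _, lengths = _run_lengths(np.asarray(seq))
        if lengths.size < 2:
            continue
        ok = lengths >= min_dwell_frames
        counts[i] = int(np.count_nonzero(ok[:-1] & ok[1:]))
    return counts, int(np.count_nonzero(counts))


def estimate_lifetime(
    n_with_transition: int,
    n_molecules: int,
    mean_observation_s: float,
    confidence: float = 0.95,
) -> KineticsEstimate:
    """Censored-fraction estimate of the conformational lifetime.

    ``fraction = n_with_transition / n_molecules`` and
    ``lifetime = mean_observation_s / fraction``; a Clopper-Pearson
    binomial interval on the fraction propagates to the lifetime.  With
    zero observed transitions the rule of three gives a lifetime *lower
    bound* ``mean_observation_s * n_molecules / 3`` (flagged).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if mean_observation_s <= 0:
        raise ValueError("mean_observation_s must be positive")
    if not 0 <= n_with_transition <= n_molecules:
        raise ValueError("n_with_transition must be in [0, n_molecules]")

    ci = stats.binomtest(n_with_transition, n_molecules).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    fraction = n_with_transition / n_molecules

    if n_with_transition == 0:
        lower_bound = mean_observation_s * n_molecules / 3.0
        return KineticsEstimate(
            n_molecules=n_molecules,
            n_with_transition=0,
            transition_fraction=0.0,
            mean_observation_s=mean_observation_s,
            lifetime_s=lower_bound,
            transition_rate_per_s=1.0 / lower_bound,
            fraction_ci=(float(ci.low), float(ci.high)),
            lifetime_ci_s=(float(mean_observation_s / ci.high), None),
            is_lower_bound=True,
        )

    lifetime = mean_observation_s / fraction
    lo = mean_observation_s / ci.high if ci.high > 0 else np.inf
    hi = mean_observation_s / ci.low if ci.low > 0 else None
    return KineticsEstimate(
        n_molecules=n_molecules,
        n_with_transition=n_with_transition,
        transition_fraction=fraction,
        mean_observation_s=mean_observation_s,
        lifetime_s=lifetime,
        transition_rate_per_s=1.0 / lifetime,
        fraction_ci=(float(ci.low), float(ci.high)),
        lifetime_ci_s=(float(lo), hi),
        is_lower_bound=False,
    )


def distance_from_efficiency(e: float, r0_nm: float) -> float:
    """Forster relation r = R0 * (1/E - 1)^(1/6), valid for 0 < E < 1."""
    if not 0.0 < e < 1.0:
        raise ValueError(f"efficiency must be in the open interval (0, 1), got {e}")
    return r0_nm * (1.0 / e - 1.0) ** (1.0 / 6.0)


def efficiency_to_distance(e: float, params: FoersterParams = FoersterParams()) -> DistanceResult:
    """Inter-dye distance for a FRET efficiency, neglecting dye size and orientation."""
    return DistanceResult(efficiency=float(e), distance_nm=distance_from_efficiency(e, params.r0_nm))


def distance_shift(e1: float, e2: float, params: FoersterParams = FoersterParams()) -> float:
    """Distance change r(E2) - r(E1) in nm (positive when E2 < E1)."""
    return distance_from_efficiency(e2, params.r0_nm) - distance_from_efficiency(e1, params.r0_nm)
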
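"""From raw two-channel traces to validated, gamma-corrected FRET efficiencies.

The chain is: detect photobleach steps on the *raw* channels (smoothing
blurs step edges), keep only molecules whose bleaching pattern proves a
single FRET pair — one acceptor bleach to background with concurrent donor
recovery and at most one final donor bleach — estimate the detection
correction factor gamma from the intensity changes across the acceptor
bleach, then compute E = I_a / (I_a + gamma * I_d) on the smoothed
pre-bleach span of each accepted trace.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    AnalysisError,
    BleachEvent,
    FretTrace,
    GammaEstimate,
    IntensityTrace,
    TraceSelection,
)

__all__ = [
    "smooth_trace",
    "moving_average",
    "detect_bleach_steps",
    "select_fret_pairs",
    "estimate_gamma",
    "compute_efficiency",
]

#: minimum raw-trace length for step detection
MIN_STEP_FRAMES = 10


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    The window of output frame ``i`` covers frames
    ``[i - (window - 1 - floor(window/2)), i + floor(window/2)]`` clipped to
    the trace, i.e. an even window extends one frame further forward than
    backward; edge frames average over whatever part of the window exists.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if n == 0:
        return x.copy()
    fwd = window // 2
    back = window - 1 - fwd
    idx = np.arange(n)
    lo = np.clip(idx - back, 0, n)
    hi = np.clip(idx + fwd + 1, 0, n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_trace(trace: IntensityTrace, window_s: float = 1.0) -> IntensityTrace:
    """Apply the centered moving average to both channels.

    ``window_s`` is converted to frames as ``round(window_s * frame_rate)``
    (minimum 1), so the default 1 s window is 10 frames at 10 fps.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    window = max(1, int(round(window_s * trace.frame_rate)))
    return IntensityTrace(
        trace.molecule_id,
        trace.frame_rate,
        moving_average(trace.donor, window),
        moving_average(trace.acceptor, window),
    )


def _best_split(x: np.ndarray, min_seg: int):
    """Best single change point of a piecewise-constant least-squares fit.

    Returns ``(k, rss, significance)`` where ``k`` is the first index of the
    right segment and ``significance = |step| / pooled within-segment sd``,
    or None when the segment is too short to split.
    """
    n = x.size
    if n < 2 * min_seg:
        return None
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    k = np.arange(min_seg, n - min_seg + 1)
    nl, nr = k, n - k
    sl, sr = c1[k], c1[n] - c1[k]
    ql, qr = c2[k], c2[n] - c2[k]
    rss = (ql - sl**2 / nl) + (qr - sr**2 / nr)
    best = int(np.argmin(rss))
    kb = int(k[best])
    step = sr[best] / nr[best] - sl[best] / nl[best]
    pooled_var = rss[best] / max(n - 2, 1)
    sd = np.sqrt(max(pooled_var, 0.0))
    if sd == 0:
        # noise-free segment: a genuine step is infinitely significant, a
        # flat stretch (step ~ 0 to rounding) is no step at all
        tiny = 1e-9 * max(1.0, float(np.max(np.abs(x))))
        significance = np.inf if abs(step) > tiny else 0.0
    else:
        significance = abs(step) / sd
    return kb, float(rss[best]), float(significance)


def detect_bleach_steps(
    trace_channel: np.ndarray,
    max_steps: int = 4,
    accept_k: float = 3.0,
    min_seg: int = 3,
    channel: str = "",
) -> list[BleachEvent]:
    """Detect intensity steps in one channel by binary segmentation.

    Repeatedly splits the segment whose best least-squares change point has
    the largest step significance (|step| / pooled within-segment sd),
    accepting splits with significance above ``accept_k``, until
    ``max_steps`` events or no acceptable split remains.  Events are
    reported in frame order with pre/post levels taken from the final
    segmentation.
    """
    x = np.asarray(trace_channel, dtype=float)
    if x.size < MIN_STEP_FRAMES:
        return []

    boundaries = [0, x.size]  # segment edges, sorted
    for _ in range(max_steps):
        best = None
        for s in range(len(boundaries) - 1):
            lo, hi = boundaries[s], boundaries[s + 1]
            res = _best_split(x[lo:hi], min_seg)
            if res is None:
                continue
            k, _, sig = res
            if sig >= accept_k and (best is None or sig > best[0]):
                best = (sig, lo + k)
        if best is None:
            break
        boundaries.append(best[1])
        boundaries.sort()

    events = []
    for s in range(1, len(boundaries) - 1):
        lo, mid, hi = boundaries[s - 1], boundaries[s], boundaries[s + 1]
        pre = float(x[lo:mid].mean())
        post = float(x[mid:hi].mean())
        events.append(BleachEvent(channel=channel, frame=mid, pre_level=pre, post_level=post))
    return events


def _is_bleach_to_background(
    event: BleachEvent, background: float, bleach_frac: float
) -> bool:
    """A *bleach* step drops to near background, unlike a partial state step."""
    amplitude = event.pre_level - background
    if amplitude <= 0:
        return False
    return event.post_level - background <= bleach_frac * amplitude


def select_fret_pairs(
    traces: list[IntensityTrace],
    events: dict[int, dict[str, list[BleachEvent]]] | None = None,
    background: float = 0.0,
    bleach_frac: float = 0.25,
    recovery_tol_frames: int = 1,
    accept_k: float = 3.0,
    max_steps: int = 4,
) -> tuple[list[TraceSelection], dict[int, dict[str, list[BleachEvent]]]]:
    """Accept only molecules whose photobleaching pattern proves a FRET pair.

    A molecule passes when (i) exactly one acceptor step drops to background
    (partial drops are candidate state transitions, not bleaches), (ii) a
    donor *increase* occurs within ``recovery_tol_frames`` of that step (the
    donor recovers when the acceptor stops accepting energy), and (iii) at
    most one donor step drops to background and, if present, it is the
    donor's final step and lies after the acceptor bleach.  Everything else
    is rejected with a reason code; rejection is an outcome, not an error.

    Returns the per-molecule selections and the (possibly computed) step
    events keyed by molecule_id.
    """
    if events is None:
        events = {
            tr.molecule_id: {
                "donor": detect_bleach_steps(
                    tr.donor, max_steps=max_steps, accept_k=accept_k, channel="donor"
                ),
                "acceptor": detect_bleach_steps(
                    tr.acceptor, max_steps=max_steps, accept_k=accept_k, channel="acceptor"
                ),
            }
            for tr in traces
        }

    selections: list[TraceSelection] = []
    for tr in traces:
        ev = events.get(tr.molecule_id, {"donor": [], "acceptor": []})
        acc_bleach = [
            e
            for e in ev["acceptor"]
            if e.delta < 0 and _is_bleach_to_background(e, background, bleach_frac)
        ]
        if len(acc_bleach) == 0:
            selections.append(TraceSelection(tr.molecule_id, False, "no_acceptor_bleach"))
            continue
        if len(acc_bleach) > 1:
            selections.append(TraceSelection(tr.molecule_id, False, "multiple_acceptor_bleach"))
            continue
        b_a = acc_bleach[0].frame

        recovery = [
            e
            for e in ev["donor"]
            if e.delta > 0 and abs(e.frame - b_a) <= recovery_tol_frames
        ]
        if not recovery:
            selections.append(
                TraceSelection(tr.molecule_id, False, "no_donor_recovery", acceptor_bleach_frame=b_a)
            )
            continue

        donor_bleach = [
            e
            for e in ev["donor"]
            if e.delta < 0 and _is_bleach_to_background(e, background, bleach_frac)
        ]
        b_d = None
        if donor_bleach:
            last_donor = ev["donor"][-1]
            ok = (
                len(donor_bleach) == 1
                and donor_bleach[0].frame == last_donor.frame
                and donor_bleach[0].frame > b_a
            )
            if not ok:
                selections.append(
                    TraceSelection(
                        tr.molecule_id, False, "bad_donor_bleach", acceptor_bleach_frame=b_a
                    )
                )
                continue
            b_d = donor_bleach[0].frame

        selections.append(
            TraceSelection(
                tr.molecule_id,
                True,
                "ok",
                acceptor_bleach_frame=b_a,
                donor_bleach_frame=b_d,
                donor_recovery_frame=recovery[0].frame,
            )
        )
    return selections, events


def estimate_gamma(
    traces: list[IntensityTrace],
    selections: list[TraceSelection],
    gamma_window_s: float = 1.0,
) -> GammaEstimate:
    """Estimate the condition-level correction factor gamma.

    Per accepted molecule, gamma_i = |dI_a / dI_d| where the intensity
    changes are mean levels over ``gamma_window_s`` immediately before
    versus after the acceptor bleach frame (the bleach frame itself is
    excluded, and the post window stops before any donor bleach).  The
    condition gamma is the median over molecules.
    """
    by_id = {tr.molecule_id: tr for tr in traces}
    values = []
    for sel in selections:
        if not sel.accepted or sel.acceptor_bleach_frame is None:
            continue
        tr = by_id[sel.molecule_id]
        b = sel.acceptor_bleach_frame
        w = max(1, int(round(gamma_window_s * tr.frame_rate)))
        pre_lo = max(0, b - w)
        post_hi = min(len(tr), b + 1 + w)
        if sel.donor_bleach_frame is not None:
            post_hi = min(post_hi, sel.donor_bleach_frame)
        if b - pre_lo < 1 or post_hi - (b + 1) < 1:
            warnings.warn(f"molecule {sel.molecule_id}: no room for gamma windows; skipped")
            continue
        d_a = tr.acceptor[b + 1 : post_hi].mean() - tr.acceptor[pre_lo:b].mean()
        d_d = tr.donor[b + 1 : post_hi].mean() - tr.donor[pre_lo:b].mean()
        if d_d == 0:
            warnings.warn(f"molecule {sel.molecule_id}: zero donor change; skipped")
            continue
        values.append(abs(d_a / d_d))
    if not values:
        raise AnalysisError("no usable molecules for gamma estimation")
    values = np.asarray(values)
    return GammaEstimate(gamma=float(np.median(values)), per_molecule_values=values, n=len(values))


def compute_efficiency(
    trace: IntensityTrace,
    gamma: float,
    bleach_frame: int | None = None,
    smooth_window_s: float | None = 1.0,
) -> FretTrace:
    """Compute the gamma-corrected FRET efficiency time series.

    Valid frames are those before ``bleach_frame`` (the acceptor bleach);
    when ``smooth_window_s`` is set, the moving average is applied to the
    valid span only, so post-bleach levels never leak into it.  Per valid
    frame, ``E = I_a / (I_a + gamma * I_d)``; frames whose denominator is
    <= 0 are marked invalid, and E is clipped to [0, 1] with the clipped
    frames recorded.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = len(trace)
    end = n if bleach_frame is None else int(np.clip(bleach_frame, 0, n))

    donor = trace.donor[:end]
    acceptor = trace.acceptor[:end]
    if smooth_window_s is not None and end > 0:
        w = max(1, int(round(smooth_window_s * trace.frame_rate)))
        donor = moving_average(donor, w)
        acceptor = moving_average(acceptor, w)

    efficiency = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    clipped = np.zeros(n, dtype=bool)

    denom = acceptor + gamma * donor
    ok = denom > 0
    raw_e = np.full(end, np.nan)
    np.divide(acceptor, denom, out=raw_e, where=ok)
    clipped[:end] = ok & ((raw_e < 0) | (raw_e > 1))
    efficiency[:end] = np.clip(raw_e, 0.0, 1.0)
    valid[:end] = ok

    if not valid.any():
        warnings.warn(f"molecule {trace.molecule_id}: no valid frames for efficiency")
        mean_e = float("nan")
    else:
        mean_e = float(np.nanmean(efficiency[valid]))

    return FretTrace(
        molecule_id=trace.molecule_id,
        frame_rate=trace.frame_rate,
        efficiency=efficiency,
        valid_mask=valid,
        gamma_used=float(gamma),
        mean_efficiency=mean_e,
        clipped_mask=clipped,
    )
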
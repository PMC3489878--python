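"""Gaussian-mixture decomposition of pooled FRET efficiencies.

Pooled per-frame efficiencies from many molecules form a multi-modal
histogram; each mode is one conformational state.  The decomposition fits a
K-component 1-D Gaussian mixture by maximum likelihood (EM on the un-binned
sample, multiple restarts with quantile-spread initial means), selects K by
BIC, names the components by descending mean (g, fg, f), and assigns each
valid frame to its maximum-posterior component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AnalysisError, FitError, FretTrace, StateAssignment, StateModel, labels_for_k

__all__ = [
    "pool_efficiencies",
    "fit_mixture",
    "fit_mixture_histogram",
    "select_k",
    "assign_states",
]

_MIN_WIDTH = 1e-4  # a component narrower than this is a degenerate collapse
_VAR_FLOOR = 1e-12


def pool_efficiencies(
    fret_traces: list[FretTrace], bin_width: float = 0.05
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate valid-frame efficiencies across molecules.

    Returns the pooled un-binned sample (the fitting unit is the frame) and
    a fixed-bin histogram over [0, 1] for reporting; fitting never uses the
    histogram.
    """
    if not fret_traces:
        raise AnalysisError("no FRET traces to pool")
    parts = [ft.valid_efficiencies for ft in fret_traces]
    sample = np.concatenate(parts) if parts else np.empty(0)
    if sample.size == 0:
        raise AnalysisError("no valid frames to pool")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(sample, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "count": counts})
    return sample, hist


def _em_once(
    x: np.ndarray,
    means0: np.ndarray,
    var0: np.ndarray,
    weights0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray] | None:
    """One EM run; returns (means, var, weights, ll, ll_path) or None if degenerate."""
    n = x.size
    means = means0.astype(float).copy()
    var = var0.astype(float).copy()
    weights = weights0.astype(float).copy()
    ll_path = []
    ll_prev = -np.inf
    xc = x[:, None]
    for _ in range(max_iter):
        comp = (weights / np.sqrt(2 * np.pi * var))[None, :] * np.exp(
            -((xc - means[None, :]) ** 2) / (2 * var[None, :])
        )
        tot = np.clip(comp.sum(axis=1), 1e-300, None)
        ll = float(np.log(tot).sum())
        ll_path.append(ll)
        resp = comp / tot[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return None
        weights = nk / n
        means = (resp * xc).sum(axis=0) / nk
        var = (resp * (xc - means[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, _VAR_FLOOR)
        if np.any(np.sqrt(var) < _MIN_WIDTH):
            return None
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return means, var, weights, ll_path[-1], np.asarray(ll_path)


def fit_mixture(
    sample: np.ndarray,
    k: int,
    n_restarts: int = 20,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StateModel:
    """Maximum-likelihood K-component Gaussian mixture on the pooled sample.

    Each restart initializes the component means at the sample quantiles of
    K sorted uniform draws ("quantile-spread": the first restart uses the
    evenly spaced quantiles (i + 0.5)/K); the best converged restart by
    log-likelihood wins.  Restarts that collapse a component (width below
    1e-4) are discarded; if all collapse a FitError is raised.  Components
    are reported sorted by ascending mean.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if x.size < 10 * k:
        raise AnalysisError(f"need at least {10 * k} samples to fit K={k}")
    rng = np.random.default_rng(seed)
    var0 = np.full(k, max(float(x.std()) / k, 1e-3) ** 2)
    w0 = np.full(k, 1.0 / k)

    # restarts run at a coarse tolerance; the winner is then polished to
    # the requested tolerance, so the returned optimum converged at `tol`
    coarse_tol = max(tol, 1e-3)
    coarse_iter = min(max_iter, 150)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            q = (np.arange(k) + 0.5) / k
        else:
            q = np.sort(rng.uniform(0.02, 0.98, size=k))
        means0 = np.quantile(x, q)
        res = _em_once(x, means0, var0, w0, coarse_tol, coarse_iter)
        if res is None:
            continue
        if best is None or res[3] > best[3]:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts degenerate for K={k}")

    polished = _em_once(x, best[0], best[1], best[2], tol, max_iter)
    if polished is not None:
        ll_path = np.concatenate([best[4], polished[4]])
        best = (*polished[:4], ll_path)
    means, var, weights, ll, ll_path = best
    widths = np.sqrt(var)
    order = np.argsort(means)
    return StateModel(
        K=k,
        means=means[order],
        widths=widths[order],
        weights=weights[order],
        state_labels=labels_for_k(k),
        log_likelihood=ll,
        n_samples=int(x.size),
        log_likelihood_path=ll_path,
    )


def fit_mixture_histogram(
    sample: np.ndarray,
    k: int,
    bin_width: float = 0.05,
    seed: int | None = None,
) -> StateModel:
    """Least-squares Gaussian-sum fit to the binned histogram.

    Fidelity-check alternative to the maximum-likelihood route: the pooled
    sample is binned over [0, 1] and a sum of K Gaussians is fit to the bin
    counts by nonlinear least squares, seeded from the ML fit.
    """
    from scipy.optimize import least_squares

    ml = fit_mixture(sample, k, n_restarts=5, seed=seed)
    x = np.asarray(sample, dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = x.size * bin_width

    def unpack(p):
        return p[:k], np.abs(p[k : 2 * k]), np.abs(p[2 * k :])

    def model(p):
        m, s, w = unpack(p)
        return (
            total
            * (w[None, :] / (np.sqrt(2 * np.pi) * s[None, :]))
            * np.exp(-((centers[:, None] - m[None, :]) ** 2) / (2 * s[None, :] ** 2))
        ).sum(axis=1)

    p0 = np.concatenate([ml.means, ml.widths, ml.weights])
    sol = least_squares(lambda p: model(p) - counts, p0, max_nfev=2000)
    m, s, w = unpack(sol.x)
    w = w / w.sum()
    order = np.argsort(m)
    return StateModel(
        K=k,
        means=m[order],
        widths=s[order],
        weights=w[order],
        state_labels=labels_for_k(k),
        log_likelihood=ml.log_likelihood,
        n_samples=int(x.size),
    )


def select_k(
    sample: np.ndarray,
    candidates: tuple[int, ...] = (2, 3),
    seed: int | None = None,
    n_restarts: int = 20,
    delta_bic_tie: float = 2.0,
    **fit_kwargs,
) -> StateModel:
    """Fit each candidate K and keep the minimum-BIC model.

    Candidate BICs within ``delta_bic_tie`` of the minimum are treated as
    ties and broken toward the smaller K (the more parsimonious state
    count).  The chosen model's ``selection_score`` records every BIC.
    """
    candidates = tuple(sorted(set(candidates)))
    if not candidates or not set(candidates) <= {1, 2, 3}:
        raise ValueError("candidates must be a non-empty subset of {1, 2, 3}")
    models = {}
    for k in candidates:
        models[k] = fit_mixture(sample, k, n_restarts=n_restarts, seed=seed, **fit_kwargs)
    bics = {k: m.bic for k, m in models.items()}
    best_bic = min(bics.values())
    chosen_k = min(k for k, b in bics.items() if b - best_bic < delta_bic_tie)
    chosen = models[chosen_k]
    chosen.selection_score = {"bic": {k: float(b) for k, b in bics.items()}}
    return chosen


def _posterior_argmax(e: np.ndarray, model: StateModel) -> np.ndarray:
    """Max-posterior component per frame; ties go to the lower-mean component."""
    log_comp = (
        np.log(model.weights)[None, :]
        - 0.5 * np.log(2 * np.pi * model.widths**2)[None, :]
        - (e[:, None] - model.means[None, :]) ** 2 / (2 * model.widths**2)[None, :]
    )
    # argmax returns the first (= lowest-mean, components sorted ascending) on ties
    return np.argmax(log_comp, axis=1)


def assign_states(
    fret_traces: FretTrace | list[FretTrace], model: StateModel
) -> StateAssignment:
    """Assign every valid frame to its maximum-posterior mixture component.

    Also reports each molecule's dominant (modal) state and the
    frame-weighted state fractions across the condition.
    """
    if isinstance(fret_traces, FretTrace):
        fret_traces = [fret_traces]
    ids, seqs, dominant = [], [], []
    counts = np.zeros(model.K)
    for ft in fret_traces:
        e = ft.valid_efficiencies
        idx = _posterior_argmax(e, model) if e.size else np.empty(0, dtype=int)
        ids.append(ft.molecule_id)
        seqs.append(idx)
        if idx.size:
            binc = np.bincount(idx, minlength=model.K)
            counts += binc
            dominant.append(model.state_labels[int(np.argmax(binc))])
        else:
            dominant.append("none")
    total = counts.sum()
    fractions = {
        lab: (float(c / total) if total > 0 else 0.0)
        for lab, c in zip(model.state_labels, counts)
    }
    return StateAssignment(
        molecule_ids=ids,
        frame_labels=seqs,
        dominant_state=dominant,
        state_fractions=fractions,
        labels=list(model.state_labels),
    )
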
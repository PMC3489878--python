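"""Dual-view spot detection, view registration and trace extraction.

A dual-view recording places the donor emission on the left half of each
frame and the acceptor emission on the right half.  The analysis needs, per
molecule, one intensity value per channel per frame; this module finds the
spots, maps donor-view positions onto the acceptor view with an affine fit,
and reads the two channels out with aperture photometry against a local
annulus background.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .types import IntensityTrace, RegistrationError, Spot, ViewRegistration

__all__ = [
    "detect_spots",
    "detect_dual_view",
    "register_views",
    "extract_traces",
]

log = logging.getLogger(__name__)


def _gaussian_refine(frame: np.ndarray, y0: int, x0: int, psf_sigma_px: float):
    """Sub-pixel 2-D Gaussian fit in a window of half-width 3*psf_sigma."""
    hw = max(2, int(np.ceil(3 * psf_sigma_px)))
    h, w = frame.shape
    ylo, yhi = max(0, y0 - hw), min(h, y0 + hw + 1)
    xlo, xhi = max(0, x0 - hw), min(w, x0 + hw + 1)
    patch = frame[ylo:yhi, xlo:xhi].astype(float)
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]

    offset0 = float(patch.min())
    amp0 = float(patch.max() - offset0)
    if amp0 <= 0:
        return None

    def resid(p):
        amp, x, y, sig, off = p
        model = off + amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sig**2))
        return (model - patch).ravel()

    p0 = [amp0, float(x0), float(y0), psf_sigma_px, offset0]
    try:
        sol = optimize.least_squares(
            resid,
            p0,
            bounds=(
                [0.0, xlo - 1, ylo - 1, 0.3, -np.inf],
                [np.inf, xhi, yhi, 5 * psf_sigma_px, np.inf],
            ),
            max_nfev=200,
        )
    except Exception:  # pragma: no cover - optimizer pathologies
        return None
    amp, x, y, _, _ = sol.x
    if amp <= 0:
        return None
    return float(x), float(y), float(amp)


def detect_spots(
    frame: np.ndarray,
    threshold_sd: float = 5.0,
    psf_sigma_px: float = 1.2,
    view: str = "donor",
) -> list[Spot]:
    """Find diffraction-limited spots in a single 2-D frame.

    Candidates are local maxima of a difference-of-Gaussians band-pass whose
    height exceeds ``background + threshold_sd * robust noise`` (median /
    MAD estimates of the filtered image); each candidate is refined to
    sub-pixel position by a 2-D Gaussian fit, and detections closer than
    ``2 * psf_sigma_px`` are merged keeping the brighter one.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")

    bp = ndimage.gaussian_filter(frame, psf_sigma_px) - ndimage.gaussian_filter(
        frame, 2.0 * psf_sigma_px
    )
    med = float(np.median(bp))
    mad = float(np.median(np.abs(bp - med)))
    noise = 1.4826 * mad
    if noise <= 0:  # constant frame
        return []
    thr = med + threshold_sd * noise

    peaks = peak_local_max(
        bp, min_distance=max(1, int(round(2 * psf_sigma_px))), threshold_abs=thr, exclude_border=False
    )
    spots: list[Spot] = []
    for y0, x0 in peaks:
        refined = _gaussian_refine(frame, int(y0), int(x0), psf_sigma_px)
        if refined is None:
            continue
        x, y, amp = refined
        spots.append(Spot(x=x, y=y, amplitude=amp, view=view))

    # merge near-duplicates, brighter wins
    spots.sort(key=lambda s: -s.amplitude)
    kept: list[Spot] = []
    for s in spots:
        if all((s.x - k.x) ** 2 + (s.y - k.y) ** 2 >= (2 * psf_sigma_px) ** 2 for k in kept):
            kept.append(s)
    kept.sort(key=lambda s: (s.y, s.x))
    return kept


def detect_dual_view(
    frame: np.ndarray, threshold_sd: float = 5.0, psf_sigma_px: float = 1.2
) -> tuple[list[Spot], list[Spot]]:
    """Detect spots separately in the two half-views of a dual-view frame.

    Returns ``(donor_spots, acceptor_spots)`` with positions in full-frame
    coordinates (the acceptor half starts at ``width // 2``).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    half = frame.shape[1] // 2
    donor = detect_spots(frame[:, :half], threshold_sd, psf_sigma_px, view="donor")
    acceptor = detect_spots(frame[:, half:], threshold_sd, psf_sigma_px, view="acceptor")
    for s in acceptor:
        s.x += half
    return donor, acceptor


def _affine_lstsq(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return coef[:2].T, coef[2]


def register_views(
    donor_spots: list[Spot],
    acceptor_spots: list[Spot],
    max_pair_dist_px: float = 4.0,
    nominal_offset_px: tuple[float, float] | None = None,
) -> ViewRegistration:
    """Fit the affine map taking donor-view positions to acceptor-view positions.

    Spots are paired by nearest neighbor after removing the nominal
    half-frame offset (estimated from coordinate medians when not given),
    then fit by least squares with one round of outlier rejection: pairs
    with residual above 3x the median residual are dropped and the fit
    repeated.
    """
    if len(donor_spots) < 3 or len(acceptor_spots) < 3:
        raise RegistrationError("need at least 3 spots in each view")

    dpos = np.array([[s.x, s.y] for s in donor_spots])
    apos = np.array([[s.x, s.y] for s in acceptor_spots])
    if nominal_offset_px is None:
        nominal = np.median(apos, axis=0) - np.median(dpos, axis=0)
    else:
        nominal = np.asarray(nominal_offset_px, dtype=float)

    shifted = dpos + nominal
    d2 = ((shifted[:, None, :] - apos[None, :, :]) ** 2).sum(axis=2)
    # greedy one-to-one matching, closest pairs first
    pairs: list[tuple[int, int]] = []
    used_d: set[int] = set()
    used_a: set[int] = set()
    for flat in np.argsort(d2, axis=None):
        i, j = np.unravel_index(flat, d2.shape)
        if i in used_d or j in used_a:
            continue
        if d2[i, j] > max_pair_dist_px**2:
            break
        pairs.append((int(i), int(j)))
        used_d.add(int(i))
        used_a.add(int(j))
    if len(pairs) < 3:
        raise RegistrationError(f"only {len(pairs)} spot pairs within {max_pair_dist_px} px")

    src = dpos[[i for i, _ in pairs]]
    dst = apos[[j for _, j in pairs]]
    matrix, offset = _affine_lstsq(src, dst)
    resid = np.linalg.norm(src @ matrix.T + offset - dst, axis=1)
    med = np.median(resid)
    keep = resid <= 3 * med if med > 0 else np.ones(len(resid), dtype=bool)
    if keep.sum() < 3:
        raise RegistrationError("fewer than 3 pairs survived outlier rejection")
    if keep.sum() < len(resid):
        matrix, offset = _affine_lstsq(src[keep], dst[keep])
        resid = np.linalg.norm(src[keep] @ matrix.T + offset - dst[keep], axis=1)

    return ViewRegistration(
        matrix=matrix,
        offset=offset,
        residual_rms_px=float(np.sqrt(np.mean(resid**2))),
        n_pairs=int(keep.sum()),
    )


def _disk_indices(x: float, y: float, radius: float, shape: tuple[int, int]):
    h, w = shape
    ylo, yhi = int(np.floor(y - radius)), int(np.ceil(y + radius)) + 1
    xlo, xhi = int(np.floor(x - radius)), int(np.ceil(x + radius)) + 1
    if ylo < 0 or xlo < 0 or yhi > h or xhi > w:
        return None
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
    return yy[mask], xx[mask]


def _annulus_indices(x: float, y: float, r_in: float, r_out: float, shape: tuple[int, int]):
    h, w = shape
    ylo, yhi = int(np.floor(y - r_out)), int(np.ceil(y + r_out)) + 1
    xlo, xhi = int(np.floor(x - r_out)), int(np.ceil(x + r_out)) + 1
    if ylo < 0 or xlo < 0 or yhi > h or xhi > w:
        return None
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    r2 = (yy - y) ** 2 + (xx - x) ** 2
    mask = (r2 >= r_in**2) & (r2 <= r_out**2)
    return yy[mask], xx[mask]


def _photometry(stack: np.ndarray, x: float, y: float, psf_sigma_px: float):
    """Aperture sum minus annulus-median background, per frame; None if clipped."""
    ap = _disk_indices(x, y, 3 * psf_sigma_px, stack.shape[1:])
    ann = _annulus_indices(x, y, 4 * psf_sigma_px, 6 * psf_sigma_px, stack.shape[1:])
    if ap is None or ann is None:
        return None
    raw = stack[:, ap[0], ap[1]].sum(axis=1)
    bg = np.median(stack[:, ann[0], ann[1]], axis=1)
    return raw - bg * len(ap[0])


def extract_traces(
    stack: np.ndarray,
    registration: ViewRegistration,
    donor_spots: list[Spot],
    psf_sigma_px: float = 1.2,
    frame_rate: float = 10.0,
) -> list[IntensityTrace]:
    """Read out per-molecule two-channel traces from a dual-view stack.

    For every donor spot the donor channel is measured at the spot position
    and the acceptor channel at the registered position in the acceptor
    view, both as the sum over a circular aperture of radius
    ``3 * psf_sigma_px`` minus the local background (annulus median at
    4-6 sigma, scaled by aperture area).  Molecules whose aperture or
    annulus leaves the frame are skipped with a logged warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected a (frames, h, w) stack, got shape {stack.shape}")

    traces: list[IntensityTrace] = []
    for i, spot in enumerate(donor_spots):
        ax, ay = registration.apply([spot.x, spot.y])[0]
        donor = _photometry(stack, spot.x, spot.y, psf_sigma_px)
        acceptor = _photometry(stack, ax, ay, psf_sigma_px)
        if donor is None or acceptor is None:
            log.warning("molecule %d skipped: aperture outside frame", i)
            continue
        traces.append(IntensityTrace(i, frame_rate, donor, acceptor))
    return traces
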
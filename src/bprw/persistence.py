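"""Persistence length of the active-crawling phase.

Experimental crawl segments are interrupted by reorientations and are too
short to estimate a persistence length directly, so crawl-only tracks are
simulated from the fitted step-length (Weibull) and turning-angle
(Gaussian) distributions and analysed with the polymer-physics end-to-end
method: the mean squared end-to-end distance as a function of contour
length L follows the worm-like-chain relation

    <R^2>(L) = 2 lp L - 2 lp^2 (1 - exp(-L / lp)),

ballistic (L^2) at short contour lengths and diffusive (2 lp L) at long
ones.  For a discrete walk with fixed step b and Gaussian turns of width
sigma the exact persistence length is lp = -b / ln<cos theta> = 2 b /
sigma^2, which the estimator must recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, NumericalError
from .params import CrawlParameters

__all__ = [
    "PersistenceEstimate",
    "simulate_crawl_only",
    "wlc_r2",
    "estimate_persistence_length",
]


@dataclass(frozen=True)
class PersistenceEstimate:
    """Fitted persistence length with fit diagnostics.

    ``lower_bound`` flags a near-ballistic ensemble (lp beyond the sampled
    contour range), where the fit constrains lp only from below.
    """

    lp: float
    fit_residual: float
    contour_range: tuple[float, float]
    lower_bound: bool = False


def simulate_crawl_only(
    params: CrawlParameters,
    n_steps: int,
    n_tracks: int,
    seed: int | None = None,
) -> np.ndarray:
    """Pure-PRW tracks: Weibull steps, Normal(0, crawl sigma) turns.

    Returns positions of shape (n_tracks, n_steps + 1, 2).  No
    reorientation events occur; this is the crawl phase in isolation.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if params.step_weibull is None or params.crawl_angle_sigma is None:
        raise DataError("crawl-only simulation needs step and angle parameters")
    k, lam = params.step_weibull
    sigma = params.crawl_angle_sigma
    rng = np.random.default_rng(seed)
    steps = lam * rng.weibull(k, size=(n_tracks, n_steps))
    turns = rng.normal(0.0, sigma, size=(n_tracks, n_steps))
    turns[:, 0] = rng.uniform(0.0, 2.0 * np.pi, size=n_tracks)
    headings = np.cumsum(turns, axis=1)
    disp = steps[..., None] * np.stack(
        [np.cos(headings), np.sin(headings)], axis=-1
    )
    pts = np.zeros((n_tracks, n_steps + 1, 2))
    pts[:, 1:] = np.cumsum(disp, axis=1)
    return pts


def wlc_r2(L: np.ndarray, lp: float) -> np.ndarray:
    """Worm-like-chain mean squared end-to-end distance at contour length L."""
    x = L / lp
    return 2.0 * lp * L - 2.0 * lp**2 * (1.0 - np.exp(-x))


def estimate_persistence_length(
    tracks: list[np.ndarray] | np.ndarray, n_bins: int = 20
) -> PersistenceEstimate:
    """Fit lp from end-to-end distances versus contour length.

    Every prefix of every track contributes one (L, R^2) pair; pairs are
    pooled into logarithmic contour-length bins between the 5th and 95th
    percentile of available L and the worm-like-chain relation is fitted to
    the bin means by least squares in linear <R^2> space.
    """
    tracks = [np.asarray(t, dtype=float) for t in tracks]
    if len(tracks) < 10:
        raise DataError("need at least 10 tracks for a persistence fit")
    if any(len(t) < 51 for t in tracks):
        raise DataError("every track needs at least 50 steps")
    Ls, R2s = [], []
    for t in tracks:
        seg = np.hypot(*np.diff(t, axis=0).T)
        L = np.cumsum(seg)
        R2 = ((t[1:] - t[0]) ** 2).sum(axis=1)
        Ls.append(L)
        R2s.append(R2)
    L = np.concatenate(Ls)
    R2 = np.concatenate(R2s)
    lo, hi = np.percentile(L, [5.0, 95.0])
    if not (hi > lo > 0):
        raise NumericalError("degenerate contour-length range")
    edges = np.geomspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(L, edges) - 1, 0, n_bins - 1)
    inside = (L >= lo) & (L <= hi)
    counts = np.bincount(which[inside], minlength=n_bins)
    if (counts > 0).sum() < 3:
        raise NumericalError("too few populated contour-length bins")
    sums_L = np.bincount(which[inside], weights=L[inside], minlength=n_bins)
    sums_R2 = np.bincount(which[inside], weights=R2[inside], minlength=n_bins)
    ok = counts > 0
    Lb = sums_L[ok] / counts[ok]
    R2b = sums_R2[ok] / counts[ok]
    mean_step = float(np.mean([np.mean(np.hypot(*np.diff(t, axis=0).T)) for t in tracks]))
    try:
        popt, _ = curve_fit(
            wlc_r2, Lb, R2b, p0=[10.0 * mean_step], maxfev=20000
        )
    except RuntimeError as exc:
        raise NumericalError(f"worm-like-chain fit failed: {exc}") from exc
    lp = float(abs(popt[0]))
    pred = wlc_r2(Lb, lp)
    residual = float(
        np.sqrt(np.mean((R2b - pred) ** 2)) / max(np.mean(R2b), 1e-300)
    )
    return PersistenceEstimate(
        lp=lp,
        fit_residual=residual,
        contour_range=(float(lo), float(hi)),
        lower_bound=bool(lp > hi),
    )
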
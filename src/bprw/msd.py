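"""Mean squared displacement of track populations.

The MSD is time-and-ensemble averaged with overlapping windows: for lag
tau, the average of |x(t + tau) - x(t)|^2 over every valid (t, track)
pair.  Its log-log slope alpha separates diffusive (alpha = 1),
superdiffusive (1 < alpha < 2) and ballistic (alpha = 2) motion; crawling
larvae are superdiffusive below their persistence time.

Confidence on a strain's population MSD comes from repeated matched
simulations: many populations of the same size as the experiment are
simulated from the strain's parameters, and the per-lag mean +/- 1 SD of
the population MSDs forms the sigma band (encompassing ~68% of matched
populations at each lag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .params import CrawlParameters
from .simulator import SimulationConfig, simulate_population
from .track_io import RawTrack

__all__ = ["MSDCurve", "default_lags", "compute_msd", "msd_sigma_band", "msd_exponent"]


@dataclass(frozen=True)
class MSDCurve:
    """Lag/value pairs in seconds and mm^2, optional 1-sigma band."""

    lags: np.ndarray  # seconds, ascending
    values: np.ndarray  # mm^2
    n_tracks: int
    sigma_band: tuple[np.ndarray, np.ndarray] | None = None  # (low, high)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if len(lags) != len(values):
            raise ValueError("lags and values must have equal length")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly ascending")


def default_lags(tracks: list[RawTrack]) -> np.ndarray:
    """Geometric-ish lag ladder (dt * Fibonacci) up to half the shortest track."""
    dt = tracks[0].dt
    max_frames = min(len(t) for t in tracks) // 2
    ladder = [0, 1]
    a, b = 1, 2
    while b <= max_frames:
        ladder.append(b)
        a, b = b, a + b
    return np.array(sorted(set(ladder)), dtype=float) * dt


def compute_msd(
    tracks: list[RawTrack], lags: np.ndarray | None = None
) -> MSDCurve:
    """Time-and-ensemble-averaged MSD of a population at the given lags."""
    if not tracks:
        raise DataError("need at least one track")
    dt = tracks[0].dt
    lags = default_lags(tracks) if lags is None else np.asarray(lags, dtype=float)
    frames = np.rint(lags / dt).astype(int)
    if np.any(np.abs(frames * dt - lags) > 1e-9 * dt):
        raise DataError("every lag must be a multiple of dt")
    values = np.empty(len(frames))
    for i, k in enumerate(frames):
        if k == 0:
            values[i] = 0.0
            continue
        total = 0.0
        count = 0
        for tr in tracks:
            if k >= len(tr.xy):
                continue
            d = tr.xy[k:] - tr.xy[:-k]
            total += float((d**2).sum())
            count += len(d)
        if count == 0:
            raise DataError(f"lag {lags[i]} s exceeds every track length")
        values[i] = total / count
    return MSDCurve(lags=lags, values=values, n_tracks=len(tracks))


def msd_sigma_band(
    params: CrawlParameters,
    n_tracks_matched: int,
    n_sims: int,
    lags: np.ndarray,
    seed: int | None = None,
    sim_config: SimulationConfig | None = None,
) -> MSDCurve:
    """Per-lag mean +/- 1 SD of population MSDs over matched simulations.

    Each of ``n_sims`` independent simulations renders a population with as
    many tracks as the experiment; the band is computed across the
    population-level MSDs, not across individual tracks.
    """
    if n_sims < 2:
        raise DataError("need at least 2 simulations for a sigma band")
    template = sim_config or SimulationConfig()
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_sims)
    curves = np.empty((n_sims, len(lags)))
    for s in range(n_sims):
        cfg = SimulationConfig(
            n_tracks=n_tracks_matched,
            duration=template.duration,
            dt=template.dt,
            seed=int(seeds[s]),
            r=template.r,
            render_jitter_sd=template.render_jitter_sd,
            crawl_span_frac=template.crawl_span_frac,
        )
        pop = simulate_population(params, cfg)
        curves[s] = compute_msd(pop, lags).values
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1)
    return MSDCurve(
        lags=np.asarray(lags, dtype=float),
        values=mean,
        n_tracks=n_tracks_matched,
        sigma_band=(mean - sd, mean + sd),
    )


def msd_exponent(curve: MSDCurve, lag_range: tuple[float, float]) -> float:
    """Least-squares log-log slope of the MSD over a lag range."""
    lo, hi = lag_range
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 3:
        raise DataError("need at least 3 lags in the fitting range")
    if np.any(curve.values[mask] <= 0):
        raise DataError("zero or negative MSD values in the fitting range")
    slope, _ = np.polyfit(
        np.log(curve.lags[mask]), np.log(curve.values[mask]), 1
    )
    return float(slope)
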
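"""Event-level bPRW simulation and rendering to raw fixed-interval samples.

A track is generated as a sequence of smoothed-point events.  Each event is
a reorientation with probability equal to the strain's reorientation
frequency (i.i.d. Bernoulli — only the mean frequency is specified by the
phenotype), otherwise an active-crawling point.  Every event is reached by
a Weibull-distributed arrival step; the heading increment before the step
is Normal(0, crawl sigma), except on exiting a reorientation, where it is
Normal(0, reorient sigma) — the broad exit turn that makes the walk
bimodal.  An event is displacement-free during its dwell, which is drawn
from the phase's Gamma model; the simulation stops once accumulated dwell
exhausts the requested duration.

Rendering expands each event into ``dwell / dt`` camera frames (stochastic
rounding, so the expected rendered duration equals the drawn dwell; events
rendering to zero frames are dropped and counted).  Crawl frames
interpolate linearly along the final stretch of the arrival step, capped
at ``crawl_span_frac * r`` so within-event motion stays below the
resolution limit — a smoothed point is by definition sub-resolution
travel.  Reorientation frames sit at the event position plus isotropic
Gaussian jitter emulating head-sweep centroid noise.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .params import CrawlParameters
from .track_io import RawTrack

__all__ = ["SimulationConfig", "EventTrack", "simulate_track", "render_raw", "simulate_population"]


@dataclass(frozen=True)
class SimulationConfig:
    """Population-level simulation and rendering settings.

    ``render_jitter_sd`` defaults to 0.2 * r: within the merge radius, so
    a reorientation episode smooths back into a single point, mimicking
    real centroid noise.
    """

    n_tracks: int = 25
    duration: float = 1800.0
    dt: float = 2.0
    seed: int | None = None
    r: float = 0.5
    render_jitter_sd: float | None = None
    crawl_span_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (self.duration > 0 and self.dt > 0 and self.r > 0):
            raise ValueError("duration, dt and r must be positive")
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
        jitter = self.jitter_sd
        if not (0.0 <= jitter < self.r / 2):
            raise ValueError("render_jitter_sd must satisfy 0 <= sd < r/2")
        if not (0.0 < self.crawl_span_frac <= 1.0):
            raise ValueError("crawl_span_frac must be in (0, 1]")

    @property
    def jitter_sd(self) -> float:
        return (
            0.2 * self.r if self.render_jitter_sd is None else self.render_jitter_sd
        )


@dataclass(frozen=True)
class EventTrack:
    """Smoothed-point-level simulated track: position, phase, dwell."""

    track_id: str
    xy: np.ndarray  # (E, 2) event positions, mm
    is_reorient: np.ndarray  # (E,) bool
    dwell: np.ndarray  # (E,) seconds

    def __len__(self) -> int:
        return len(self.dwell)


def _require_complete(params: CrawlParameters) -> None:
    if not params.is_complete():
        raise DataError(
            "simulation requires a complete parameter set (no degenerate fields)"
        )


def simulate_track(
    params: CrawlParameters,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    track_id: str = "sim",
) -> EventTrack:
    """Generate one event-level bPRW track of at least ``config.duration``."""
    _require_complete(params)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    f = params.reorientation_frequency
    kc, sc = params.crawl_time_gamma
    kr, sr = params.reorient_time_gamma
    wk, wlam = params.step_weibull
    sig_c = params.crawl_angle_sigma
    sig_r = params.reorient_angle_sigma

    mean_dwell = (1 - f) * kc * sc + f * kr * sr
    positions = [np.zeros(2)]
    phases: list[bool] = []
    dwells: list[float] = []
    heading = rng.uniform(0.0, 2.0 * np.pi)
    total = 0.0
    first = True
    # draw in blocks for speed; the walk itself is inherently sequential in
    # heading, but heading increments can be pre-drawn as standard normals
    block = max(16, int(config.duration / max(mean_dwell, 1e-9) * 1.2) + 8)
    while total < config.duration:
        reo = rng.random(block) < f
        steps = wlam * rng.weibull(wk, block)
        z = rng.standard_normal(block)
        dwell_c = rng.gamma(kc, sc, block)
        dwell_r = rng.gamma(kr, sr, block)
        for i in range(block):
            if total >= config.duration:
                break
            if first:
                first = False
            else:
                prev_reorient = phases[-1]
                heading += z[i] * (sig_r if prev_reorient else sig_c)
                positions.append(
                    positions[-1]
                    + steps[i] * np.array([np.cos(heading), np.sin(heading)])
                )
            d = dwell_r[i] if reo[i] else dwell_c[i]
            phases.append(bool(reo[i]))
            dwells.append(float(d))
            total += d
    return EventTrack(
        track_id=track_id,
        xy=np.array(positions),
        is_reorient=np.array(phases, dtype=bool),
        dwell=np.array(dwells),
    )


def render_raw(
    events: EventTrack,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> RawTrack:
    """Render an event track to fixed-interval raw centroid samples."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    dt = config.dt
    E = len(events)
    frac, whole = np.modf(events.dwell / dt)
    n = whole.astype(np.int64) + (rng.random(E) < frac)
    dropped = int((n == 0).sum())
    if dropped:
        _warnings.warn(
            f"{dropped} event(s) shorter than the frame interval were dropped",
            stacklevel=2,
        )
    keep = n > 0
    xy_e = events.xy[keep]
    reo_e = events.is_reorient[keep]
    n = n[keep]
    if n.sum() < 2:
        raise DataError("rendered track has fewer than 2 samples")
    # incoming unit vectors (first event has no incoming step)
    vin = np.zeros_like(events.xy)
    vin[1:] = np.diff(events.xy, axis=0)
    vin = vin[keep]
    norms = np.hypot(vin[:, 0], vin[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms[:, None] > 0, vin / np.maximum(norms, 1e-300)[:, None], 0.0)
    span = np.minimum(norms, config.crawl_span_frac * config.r)

    total = int(n.sum())
    ev = np.repeat(np.arange(len(n)), n)  # per-sample event index
    offsets = np.concatenate(([0], np.cumsum(n)[:-1]))
    j = np.arange(total) - np.repeat(offsets, n)  # within-event rank 0..n-1
    ne = n[ev]
    back = (ne - 1 - j) / ne  # fraction of the span still to travel
    pos = xy_e[ev] - back[:, None] * span[ev, None] * unit[ev]
    jitter_mask = reo_e[ev]
    n_jit = int(jitter_mask.sum())
    if n_jit and config.jitter_sd > 0:
        pos[jitter_mask] = xy_e[ev[jitter_mask]] + config.jitter_sd * rng.standard_normal(
            (n_jit, 2)
        )
    elif n_jit:
        pos[jitter_mask] = xy_e[ev[jitter_mask]]
    return RawTrack(track_id=events.track_id, dt=dt, xy=pos)


def simulate_population(
    params: CrawlParameters, config: SimulationConfig
) -> list[RawTrack]:
    """Simulate and render ``n_tracks`` independent tracks.

    Per-track generators are spawned deterministically from the master
    seed, so the same seed reproduces the population bit-for-bit.
    """
    _require_complete(params)
    master = np.random.default_rng(config.seed)
    children = master.spawn(config.n_tracks)
    out = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for i, child in enumerate(children):
            ev = simulate_track(params, config, rng=child, track_id=f"sim{i:03d}")
            out.append(render_raw(ev, config, rng=child))
    return out


def simulate_event_population(
    params: CrawlParameters, config: SimulationConfig
) -> list[EventTrack]:
    """Event-level population (no rendering), same seeding scheme."""
    _require_complete(params)
    master = np.random.default_rng(config.seed)
    return [
        simulate_track(params, config, rng=child, track_id=f"sim{i:03d}")
        for i, child in enumerate(master.spawn(config.n_tracks))
    ]
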
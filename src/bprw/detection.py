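"""Phase classification: reorientation events and pathological rests.

Reorientation shows up in smoothed tracks as points with markedly large m
(the larva stands still and head-sweeps, piling raw samples into one
smoothed point).  Because strains differ in speed, no fixed m threshold
works; instead each track's m vector is screened with the modified
Thompson tau test — an adaptive, roughly two-sigma outlier criterion —
and the high-side outliers are labeled REORIENT.

Separately, rarely, injured larvae rest in one spot for very long; any
point dwelling strictly longer than ``rest_threshold`` (default 14 s) is
excluded from all downstream statistics.  The rest filter runs before the
tau screen so pathological resting cannot mask genuine reorientations;
crawl segments are broken at interior exclusions so no step is fabricated
across an excluded gap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .smoothing import SmoothedTrack
from .track_io import AnalysisConfig

__all__ = [
    "Phase",
    "PhaseLabeledTrack",
    "thompson_tau_outliers",
    "rest_filter",
    "detect_reorientations",
]

_ALPHA = 0.05


class Phase(enum.IntEnum):
    CRAWL = 0
    REORIENT = 1


@dataclass(frozen=True)
class PhaseLabeledTrack:
    """Smoothed track plus per-point phase labels and rest exclusions.

    ``rest_excluded`` marks points removed from statistics by the rest
    filter; such points keep the CRAWL label but are never counted.
    ``too_short`` flags tracks with fewer than 3 usable points, which are
    labeled entirely CRAWL by convention.
    """

    track_id: str
    dt: float
    xy: np.ndarray
    m: np.ndarray
    labels: np.ndarray  # (n,) int, Phase values
    rest_excluded: np.ndarray  # (n,) bool
    too_short: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rest_excluded", np.asarray(self.rest_excluded, dtype=bool)
        )
        n = len(self.m)
        if not (len(self.labels) == n and len(self.rest_excluded) == n):
            raise ValueError("labels/rest_excluded must match point count")

    def __len__(self) -> int:
        return len(self.m)

    @property
    def dwell_times(self) -> np.ndarray:
        return self.m * self.dt

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of points that count toward statistics."""
        return ~self.rest_excluded

    def phase_strings(self) -> np.ndarray:
        """Per-point CSV label: CRAWL / REORIENT / REST_EXCLUDED."""
        out = np.where(
            self.labels == Phase.REORIENT, "REORIENT", "CRAWL"
        ).astype(object)
        out[self.rest_excluded] = "REST_EXCLUDED"
        return out


def modified_tau(n: int, alpha: float = _ALPHA) -> float:
    """Modified Thompson tau critical multiple for sample size n.

    tau = t * (n - 1) / (sqrt(n) * sqrt(n - 2 + t^2)) with t the two-tailed
    Student-t quantile at ``alpha``, df = n - 2.
    """
    if n < 3:
        raise ValueError("tau undefined for n < 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t * t)))


def thompson_tau_outliers(values: np.ndarray, alpha: float = _ALPHA) -> set[int]:
    """Iterative modified-Thompson outlier screen; returns flagged indices.

    Each round computes the sample mean and SD (ddof=1) of the surviving
    values, takes the value with the largest absolute deviation (first
    index on ties), flags it if its deviation exceeds tau * SD, removes it,
    and repeats until nothing is flagged or fewer than 3 values survive.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(v) < 3:
        raise ValueError("Thompson tau requires at least 3 values")
    active = np.arange(len(v))
    flagged: set[int] = set()
    while len(active) >= 3:
        sample = v[active]
        mean = sample.mean()
        sd = sample.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sample - mean)
        k = int(np.argmax(dev))
        if dev[k] > modified_tau(len(active), alpha) * sd:
            flagged.add(int(active[k]))
            active = np.delete(active, k)
        else:
            break
    return flagged


def rest_filter(
    track: SmoothedTrack, config: AnalysisConfig
) -> tuple[SmoothedTrack, np.ndarray]:
    """Mark points whose dwell m*dt strictly exceeds the rest threshold.

    Returns the (unchanged) track and a boolean exclusion mask; a dwell of
    exactly the threshold is retained ("more than" is strict).
    """
    excluded = track.dwell_times > config.rest_threshold
    return track, excluded


def detect_reorientations(
    track: SmoothedTrack, config: AnalysisConfig | None = None
) -> PhaseLabeledTrack:
    """Label each smoothed point CRAWL or REORIENT.

    Applies the rest filter, runs the tau screen on the m values of the
    remaining points, and labels REORIENT only the flagged points whose m
    lies above the post-removal mean (the screen is two-sided, but only
    "the largest values" are reorientations).  Tracks with fewer than 3
    usable points come back all-CRAWL with ``too_short`` set.
    """
    config = config or AnalysisConfig(dt=track.dt)
    _, excluded = rest_filter(track, config)
    labels = np.full(len(track), int(Phase.CRAWL), dtype=np.int64)
    included_idx = np.flatnonzero(~excluded)
    if len(included_idx) < 3:
        return PhaseLabeledTrack(
            track_id=track.track_id,
            dt=track.dt,
            xy=track.xy,
            m=track.m,
            labels=labels,
            rest_excluded=excluded,
            too_short=True,
        )
    m_incl = track.m[included_idx].astype(float)
    flagged_local = thompson_tau_outliers(m_incl)
    survivors = np.delete(m_incl, sorted(flagged_local)) if flagged_local else m_incl
    post_mean = survivors.mean()
    for loc in flagged_local:
        if m_incl[loc] > post_mean:
            labels[included_idx[loc]] = int(Phase.REORIENT)
    return PhaseLabeledTrack(
        track_id=track.track_id,
        dt=track.dt,
        xy=track.xy,
        m=track.m,
        labels=labels,
        rest_excluded=excluded,
        too_short=False,
    )
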
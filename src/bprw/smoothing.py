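"""Resolution-limit smoothing of raw centroid trajectories.

A crawling larva imaged every couple of seconds produces centroid samples
whose spacing reflects its speed: fast crawling spreads samples apart,
while reorientation (still-standing, head-sweeping) piles them up within
the imaging resolution.  Smoothing collapses each run of samples that stay
within a merge radius of the run's first sample into a single point, and
records in ``m`` how many raw samples that point absorbed — so ``m * dt``
is the dwell time at the point, the temporal signal all later analysis
rests on.

The walk is greedy and sequential: starting from the first sample, the
distance to each consecutive sample is measured from the run's anchor (its
first member); the run ends at the first sample farther than the threshold,
which then anchors the next run.  Each run is replaced by the m-weighted
centroid of its members.  To reach the finest possible smoothing the pass
is repeated with thresholds a*r for a = 1/K, 2/K, ..., 1, each pass
consuming the previous pass's output, and finally iterated at threshold r
until a fixed point (so consecutive output points are all > r apart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .track_io import AnalysisConfig, RawTrack

__all__ = ["SmoothedTrack", "merge_pass", "smooth_track"]

#: Safety cap on the final fixed-point iteration (usually 0-1 extra passes).
_MAX_FIXED_POINT_PASSES = 100


@dataclass(frozen=True)
class SmoothedTrack:
    """Smoothed points (x, y, m); sum(m) equals the raw sample count."""

    track_id: str
    dt: float
    xy: np.ndarray  # (n, 2) float
    m: np.ndarray  # (n,) int, m >= 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "xy", np.asarray(self.xy, dtype=float))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=np.int64))
        if len(self.xy) != len(self.m):
            raise ValueError("xy and m must have equal length")
        if np.any(self.m < 1):
            raise ValueError("every m must be >= 1")

    def __len__(self) -> int:
        return len(self.m)

    @property
    def dwell_times(self) -> np.ndarray:
        """Seconds spent at each smoothed point, m * dt."""
        return self.m * self.dt


def merge_pass(
    xy: np.ndarray, m: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """One greedy merge pass over an ordered (x, y, m) sequence.

    Runs of consecutive points within ``threshold`` (inclusive: boundary
    ties merge) of the run's first member collapse to their m-weighted
    centroid; m values add, so total m is conserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    xy = np.asarray(xy, dtype=float)
    m = np.asarray(m, dtype=np.int64)
    n = len(xy)
    if n == 0:
        raise ValueError("empty point sequence")
    out_xy: list[np.ndarray] = []
    out_m: list[int] = []
    i = 0
    while i < n:
        anchor = xy[i]
        j = i + 1
        while j < n and np.hypot(*(xy[j] - anchor)) <= threshold:
            j += 1
        run_m = m[i:j]
        total = int(run_m.sum())
        centroid = (xy[i:j] * run_m[:, None]).sum(axis=0) / total
        out_xy.append(centroid)
        out_m.append(total)
        i = j
    return np.array(out_xy), np.array(out_m, dtype=np.int64)


def smooth_track(raw: RawTrack, config: AnalysisConfig) -> SmoothedTrack:
    """Smooth a raw track with the escalating-threshold schedule.

    Thresholds a*r for a = 1/K ... 1 (K = ``config.smoothing_steps``), then
    a fixed-point iteration at r.  Raw samples start with m = 1 and m sums
    on every merge, so sum(m) always equals the raw sample count.
    """
    if len(raw.xy) < 2:
        raise DataError(f"track {raw.track_id!r}: too short to smooth")
    r = config.resolution_limit_r
    K = config.smoothing_steps
    xy = raw.xy
    m = np.ones(len(xy), dtype=np.int64)
    for step in range(1, K + 1):
        xy, m = merge_pass(xy, m, (step / K) * r)
    for _ in range(_MAX_FIXED_POINT_PASSES):
        new_xy, new_m = merge_pass(xy, m, r)
        if len(new_m) == len(m):
            break
        xy, m = new_xy, new_m
    return SmoothedTrack(track_id=raw.track_id, dt=raw.dt, xy=xy, m=m)
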
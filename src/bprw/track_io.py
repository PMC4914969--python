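"""Trajectory containers and tabular IO.

Tracks are fixed-interval centroid samples of a crawling larva: one row per
video frame, positions in mm.  Internally everything is mm and seconds.
Input tables may carry either an absolute time column (seconds) or a frame
index; sampling regularity is enforced strictly, since frame-timestamped
exports are exact and anything else signals corrupt input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, IrregularSamplingError
from .params import (
    CrawlParameters,
    read_parameters_json,
    write_parameters_json,
)

__all__ = [
    "RawTrack",
    "AnalysisConfig",
    "Dialect",
    "read_tracks",
    "write_tracks",
    "write_parameters",
    "read_parameters",
]

#: Relative tolerance on per-frame interval deviation, |dt_i - dt| <= RTOL * dt.
SAMPLING_RTOL = 1e-6


@dataclass(frozen=True)
class RawTrack:
    """One larva's trajectory: (x, y) in mm sampled every ``dt`` seconds."""

    track_id: str
    dt: float
    xy: np.ndarray  # shape (n, 2), float64

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(xy) < 2:
            raise DataError(f"track {self.track_id!r}: needs at least 2 points")
        if not np.all(np.isfinite(xy)):
            raise DataError(f"track {self.track_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def duration(self) -> float:
        """Total track duration in seconds."""
        return (len(self.xy) - 1) * self.dt


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the smoothing/detection pipeline.

    ``resolution_limit_r`` is the merge radius in mm — empirically the
    nominal width of a larva in the camera image.  ``smoothing_steps`` is
    the number of threshold-escalation passes (thresholds a*r with a rising
    from 1/K to 1).  ``rest_threshold`` (seconds) excludes still-standing
    points dwelling strictly longer than this; it may be ``inf`` to disable
    the filter for data known to contain no resting pathology.
    """

    resolution_limit_r: float = 0.5
    smoothing_steps: int = 10
    rest_threshold: float = 14.0
    dt: float = 2.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.resolution_limit_r > 0):
            raise ValueError("resolution_limit_r must be positive")
        if self.smoothing_steps < 1:
            raise ValueError("smoothing_steps must be >= 1")
        if not (self.rest_threshold > 0):
            raise ValueError("rest_threshold must be positive")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class Dialect:
    """Column mapping for trajectory tables.

    ``time`` may name either an absolute-time column (seconds) or a frame
    index; set ``time_is_frame`` accordingly.  ``scale_xy`` converts input
    position units to mm.
    """

    track_id: str = "track_id"
    time: str = "t_s"
    x: str = "x_mm"
    y: str = "y_mm"
    time_is_frame: bool = False
    scale_xy: float = 1.0


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_tracks(
    path: str | Path,
    dialect: Dialect | None = None,
    dt: float | None = None,
) -> list[RawTrack]:
    """Read a delimited trajectory table into one :class:`RawTrack` per id.

    Rows are sorted by time within each track; the sampling interval is
    inferred from the time column (or taken from ``dt`` for frame-indexed
    tables, default 2 s) and checked for strict regularity.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"trajectory file not found: {path}")
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=_infer_sep(path))
    needed = [dialect.track_id, dialect.time, dialect.x, dialect.y]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    for col in (dialect.time, dialect.x, dialect.y):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise DataError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise DataError(f"{path}: missing value in column {col!r} at row {row}")
        df[col] = coerced

    tracks: list[RawTrack] = []
    for tid, group in df.groupby(dialect.track_id, sort=True):
        group = group.sort_values(dialect.time, kind="stable")
        t = group[dialect.time].to_numpy(dtype=float)
        if dialect.time_is_frame:
            track_dt = dt if dt is not None else 2.0
            steps = np.diff(t)
            if len(steps) and not np.all(steps == 1):
                raise IrregularSamplingError(
                    f"track {tid!r}: irregular sampling (non-consecutive frames)"
                )
        else:
            steps = np.diff(t)
            if len(steps) == 0:
                raise DataError(f"track {tid!r}: needs at least 2 points")
            track_dt = float(steps[0]) if dt is None else float(dt)
            if track_dt <= 0 or np.any(
                np.abs(steps - track_dt) > SAMPLING_RTOL * track_dt
            ):
                raise IrregularSamplingError(
                    f"track {tid!r}: irregular sampling interval "
                    f"(expected {track_dt} s)"
                )
        xy = group[[dialect.x, dialect.y]].to_numpy(dtype=float) * dialect.scale_xy
        tracks.append(RawTrack(track_id=str(tid), dt=track_dt, xy=xy))
    return tracks


def write_tracks(
    tracks: list[RawTrack], path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write tracks to a delimited table in the given dialect (absolute time)."""
    dialect = dialect or Dialect()
    path = Path(path)
    frames = []
    for tr in tracks:
        t = np.arange(len(tr.xy)) * (1.0 if dialect.time_is_frame else tr.dt)
        frames.append(
            pd.DataFrame(
                {
                    dialect.track_id: tr.track_id,
                    dialect.time: t,
                    dialect.x: tr.xy[:, 0] / dialect.scale_xy,
                    dialect.y: tr.xy[:, 1] / dialect.scale_xy,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[dialect.track_id, dialect.time, dialect.x, dialect.y]
    )
    out.to_csv(path, sep=_infer_sep(path), index=False)


def write_parameters(params: CrawlParameters, path: str | Path) -> None:
    """Serialise a parameter set to JSON (lossless round trip)."""
    write_parameters_json(params, path)


def read_parameters(path: str | Path) -> CrawlParameters:
    """Read a parameter set written by :func:`write_parameters`."""
    p = Path(path)
    if not p.exists():
        raise DataError(f"parameter file not found: {p}")
    return read_parameters_json(p)
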
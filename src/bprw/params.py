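"""The crawl phenotype: parameters of the bimodal persistent random walk.

A strain's crawling behaviour is condensed into six quantities measured on
smoothed, phase-labeled tracks:

1. the mean fraction of smoothed points that are reorientation events,
2. a Gamma model of the dwell time per active-crawling point,
3. a Gamma model of the dwell time per reorientation point,
4. a Weibull model of the step length between consecutive crawl points,
5. the Gaussian sigma of turning angles between consecutive crawl steps,
6. the Gaussian sigma of the turn across a reorientation event.

Together these drive the simulator and summarise a strain for comparison.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import SchemaError

__all__ = ["CrawlParameters", "parameters_to_dict", "parameters_from_dict"]


@dataclass(frozen=True)
class CrawlParameters:
    """Strain-level phenotype extracted from (or driving) crawl trajectories.

    Dwell-time Gammas are ``(shape, scale)`` in seconds; the step model is
    ``(k, lambda)`` of a Weibull in mm; angle sigmas are in radians.  Fields
    may be ``None`` when a phase was absent from the data (degenerate fit);
    such parameter sets cannot be simulated from.
    """

    reorientation_frequency: float
    crawl_time_gamma: tuple[float, float] | None
    reorient_time_gamma: tuple[float, float] | None
    step_weibull: tuple[float, float] | None
    crawl_angle_sigma: float | None
    reorient_angle_sigma: float | None

    def __post_init__(self) -> None:
        f = self.reorientation_frequency
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"reorientation_frequency must be in [0, 1], got {f}")
        for name in ("crawl_time_gamma", "reorient_time_gamma", "step_weibull"):
            pair = getattr(self, name)
            if pair is not None and not all(
                math.isfinite(v) and v > 0 for v in pair
            ):
                raise ValueError(f"{name} must be a pair of positive finite numbers")
        for name in ("crawl_angle_sigma", "reorient_angle_sigma"):
            sig = getattr(self, name)
            if sig is not None and not (math.isfinite(sig) and sig >= 0):
                raise ValueError(f"{name} must be a non-negative finite number")

    @property
    def crawl_dwell_mean(self) -> float | None:
        """Mean crawl dwell time in seconds (shape * scale)."""
        g = self.crawl_time_gamma
        return None if g is None else g[0] * g[1]

    @property
    def reorient_dwell_mean(self) -> float | None:
        """Mean reorientation dwell time in seconds (shape * scale)."""
        g = self.reorient_time_gamma
        return None if g is None else g[0] * g[1]

    @property
    def mean_step_length(self) -> float | None:
        """Mean crawl step length in mm, lambda * Gamma(1 + 1/k)."""
        w = self.step_weibull
        if w is None:
            return None
        k, lam = w
        return lam * math.gamma(1.0 + 1.0 / k)

    def is_complete(self) -> bool:
        """True when every field is present (required for simulation)."""
        return all(
            getattr(self, f.name) is not None for f in dataclasses.fields(self)
        )


_REQUIRED_FIELDS = [f.name for f in dataclasses.fields(CrawlParameters)]


def parameters_to_dict(params: CrawlParameters) -> dict:
    d = {}
    for name in _REQUIRED_FIELDS:
        value = getattr(params, name)
        d[name] = list(value) if isinstance(value, tuple) else value
    return d


def parameters_from_dict(d: dict) -> CrawlParameters:
    missing = [name for name in _REQUIRED_FIELDS if name not in d]
    if missing:
        raise SchemaError(f"parameter file missing required field(s): {missing}")
    kwargs = {}
    for name in _REQUIRED_FIELDS:
        value = d[name]
        if isinstance(value, (list, tuple)):
            if len(value) != 2:
                raise SchemaError(f"field {name} must have exactly two entries")
            value = (float(value[0]), float(value[1]))
        elif value is not None:
            value = float(value)
        kwargs[name] = value
    try:
        return CrawlParameters(**kwargs)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def write_parameters_json(params: CrawlParameters, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(parameters_to_dict(params), indent=2, sort_keys=True) + "\n"
    )


def read_parameters_json(path: str | Path) -> CrawlParameters:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    return parameters_from_dict(d)
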
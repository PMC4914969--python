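"""Phenotype extraction from phase-labeled tracks.

Active crawling is a persistent random walk: step lengths between
consecutive smoothed crawl points follow a Weibull distribution and the
turning angles between consecutive crawl steps are zero-mean Gaussian.
Dwell times per point in each phase are modeled as Gamma distributions
(long-tailed), and the turn across a reorientation event — incoming versus
outgoing crawl displacement — is Gaussian with a much larger sigma, fitted
after iterative Grubbs outlier removal because those samples are few.

Population statistics follow the per-track-first convention: a quantity is
computed per track, then reported as mean +/- SEM across tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detection import Phase, PhaseLabeledTrack, detect_reorientations
from .errors import DataError, NumericalError
from .params import CrawlParameters
from .smoothing import smooth_track
from .track_io import AnalysisConfig, RawTrack

__all__ = [
    "FitReport",
    "PopulationStat",
    "ExtractionResult",
    "turning_angles",
    "crawl_segments",
    "step_lengths",
    "crawl_turning_angles",
    "reorientation_turns",
    "fit_distribution",
    "select_best",
    "reorientation_frequency",
    "agility",
    "agility_ratio",
    "grubbs_filter",
    "fit_reorientation_turn_sigma",
    "extract_parameters",
]

_GRUBBS_ALPHA = 0.05

#: Candidate families for maximum-likelihood model comparison.  Positive-
#: support families are fitted with the location pinned at zero.
_FAMILIES: dict[str, tuple[stats.rv_continuous, dict, int]] = {
    "weibull": (stats.weibull_min, {"floc": 0.0}, 2),
    "normal": (stats.norm, {}, 2),
    "gamma": (stats.gamma, {"floc": 0.0}, 2),
    "lognormal": (stats.lognorm, {"floc": 0.0}, 2),
    "exponential": (stats.expon, {"floc": 0.0}, 1),
    "cauchy": (stats.cauchy, {}, 2),
}
_POSITIVE_SUPPORT = {"weibull", "gamma", "lognormal", "exponential"}


@dataclass(frozen=True)
class FitReport:
    """Maximum-likelihood fit of one candidate family."""

    family: str
    log_likelihood: float
    aic: float
    params: dict[str, float]
    stderr: dict[str, float | None]
    n: int


@dataclass(frozen=True)
class PopulationStat:
    """Across-track mean +/- SEM; ``n`` counts contributing tracks."""

    mean: float
    sem: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0


# ---------------------------------------------------------------------------
# geometry


def signed_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Signed angle from v1 to v2 in (-pi, pi]; positive = counter-clockwise."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return math.atan2(cross, dot)


def turning_angles(
    xy: np.ndarray, stride: int = 1, return_skipped: bool = False
):
    """Signed turning angles between consecutive displacement vectors.

    ``stride`` re-samples the sequence at stride * dt before forming
    displacements, reproducing coarser sampling intervals.  Zero-length
    displacements make an angle undefined; those angles are skipped and
    (optionally) counted.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pts = np.asarray(xy, dtype=float)[::stride]
    if len(pts) < 3:
        raise DataError("need at least 3 points after stride subsampling")
    v = np.diff(pts, axis=0)
    norms = np.hypot(v[:, 0], v[:, 1])
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    dot = (v[:-1] * v[1:]).sum(axis=1)
    ok = (norms[:-1] > 0) & (norms[1:] > 0)
    angles = np.arctan2(cross[ok], dot[ok])
    if return_skipped:
        return angles, int((~ok).sum())
    return angles


# ---------------------------------------------------------------------------
# segment bookkeeping


def crawl_segments(labeled: PhaseLabeledTrack) -> list[np.ndarray]:
    """Maximal runs of consecutive CRAWL points usable for step statistics.

    Runs break at REORIENT points and at rest-excluded points, so no step
    or angle ever spans a reorientation or an excluded gap.
    """
    usable = (labeled.labels == int(Phase.CRAWL)) & labeled.included
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) != 1)
    return [seg for seg in np.split(idx, breaks + 1) if len(seg) >= 2]


def step_lengths(labeled: PhaseLabeledTrack) -> np.ndarray:
    """Euclidean distances between consecutive crawl points within segments."""
    out = []
    for seg in crawl_segments(labeled):
        d = np.diff(labeled.xy[seg], axis=0)
        out.append(np.hypot(d[:, 0], d[:, 1]))
    return np.concatenate(out) if out else np.empty(0)


def crawl_turning_angles(labeled: PhaseLabeledTrack) -> np.ndarray:
    """Turning angles between consecutive crawl steps within segments."""
    out = []
    for seg in crawl_segments(labeled):
        if len(seg) >= 3:
            out.append(turning_angles(labeled.xy[seg]))
    return np.concatenate(out) if out else np.empty(0)


def reorientation_turns(labeled: PhaseLabeledTrack) -> np.ndarray:
    """Turn across each reorientation event.

    The angle between the displacement into the REORIENT point and the
    displacement out of it, for events whose immediate neighbours are
    usable crawl points.
    """
    lab = labeled.labels
    incl = labeled.included
    xy = labeled.xy
    turns = []
    for k in np.flatnonzero((lab == int(Phase.REORIENT)) & incl):
        if k == 0 or k == len(lab) - 1:
            continue
        if lab[k - 1] != int(Phase.CRAWL) or lab[k + 1] != int(Phase.CRAWL):
            continue
        if not (incl[k - 1] and incl[k + 1]):
            continue
        v_in = xy[k] - xy[k - 1]
        v_out = xy[k + 1] - xy[k]
        if np.hypot(*v_in) == 0 or np.hypot(*v_out) == 0:
            continue
        turns.append(signed_angle(v_in, v_out))
    return np.asarray(turns)


# ---------------------------------------------------------------------------
# distribution fitting


def _negative_loglik(dist, data, free_names, fixed, values):
    kwargs = dict(zip(free_names, values))
    kwargs.update(fixed)
    return -np.sum(dist.logpdf(data, **kwargs))


def _standard_errors(dist, data, shape_names, mle, fixed) -> dict:
    """Observed-information standard errors via a finite-difference Hessian."""
    free_names = [n for n in shape_names if n not in fixed]
    theta = np.array([mle[n] for n in free_names], dtype=float)
    h = np.maximum(np.abs(theta), 1.0) * 1e-4
    k = len(theta)
    H = np.empty((k, k))

    def f(x):
        return _negative_loglik(dist, data, free_names, fixed, x)

    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    se: dict[str, float | None] = {n: None for n in shape_names}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            for n, s in zip(free_names, np.sqrt(diag)):
                se[n] = float(s)
    except np.linalg.LinAlgError:
        pass
    return se


def _param_names(dist) -> list[str]:
    shapes = [s.strip() for s in dist.shapes.split(",")] if dist.shapes else []
    return shapes + ["loc", "scale"]


def fit_distribution(samples: np.ndarray, family: str) -> FitReport:
    """MLE fit of one family; reports log-likelihood and AIC.

    Positive-support families (weibull, gamma, lognormal, exponential) pin
    the location at zero and reject non-positive samples.  A constant
    sample is degenerate for every family and raises.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    x = np.asarray(samples, dtype=float)
    if len(x) < 20:
        raise DataError(f"need at least 20 samples to fit {family} (got {len(x)})")
    if np.ptp(x) == 0:
        raise NumericalError(f"degenerate fit: constant sample for family {family}")
    dist, fit_kwargs, n_free = _FAMILIES[family]
    if family in _POSITIVE_SUPPORT and np.any(x <= 0):
        raise DataError(f"family {family} requires strictly positive samples")
    try:
        mle_tuple = dist.fit(x, **fit_kwargs)
    except Exception as exc:  # scipy raises various types on failure
        raise NumericalError(f"MLE fit failed for family {family}: {exc}") from exc
    names = _param_names(dist)
    mle = dict(zip(names, (float(v) for v in mle_tuple)))
    ll = float(np.sum(dist.logpdf(x, *mle_tuple)))
    if not np.isfinite(ll):
        raise NumericalError(f"non-finite likelihood for family {family}")
    fixed = {"loc": 0.0} if "floc" in fit_kwargs else {}
    if family == "exponential":
        fixed = {"loc": 0.0}
    se = _standard_errors(dist, x, names, mle, fixed)
    return FitReport(
        family=family,
        log_likelihood=ll,
        aic=2 * n_free - 2 * ll,
        params=mle,
        stderr=se,
        n=len(x),
    )


def select_best(
    samples: np.ndarray, families: tuple[str, ...] | None = None
) -> tuple[FitReport, list[FitReport]]:
    """Fit every applicable candidate family and pick the minimum-AIC one."""
    families = families or tuple(_FAMILIES)
    reports = []
    for fam in families:
        try:
            reports.append(fit_distribution(samples, fam))
        except (DataError, NumericalError):
            continue
    if not reports:
        raise NumericalError("no candidate family could be fitted")
    reports.sort(key=lambda r: r.aic)
    return reports[0], reports


# ---------------------------------------------------------------------------
# population statistics


def _population(values: list[float]) -> PopulationStat:
    if not values:
        return PopulationStat(mean=float("nan"), sem=float("nan"), n=0)
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return PopulationStat(mean=float(arr.mean()), sem=sem, n=len(arr))


def reorientation_frequency(tracks: list[PhaseLabeledTrack]) -> PopulationStat:
    """Fraction of (included) smoothed points labeled REORIENT.

    Computed per track, then averaged across tracks with the SEM over
    tracks.
    """
    if not tracks:
        raise DataError("need at least one labeled track")
    fracs = []
    for tr in tracks:
        n_incl = int(tr.included.sum())
        if n_incl == 0:
            continue
        n_reo = int(((tr.labels == int(Phase.REORIENT)) & tr.included).sum())
        fracs.append(n_reo / n_incl)
    return _population(fracs)


def agility(tracks: list[PhaseLabeledTrack], phase: Phase) -> PopulationStat:
    """Inverse mean dwell time per point of a phase, in 1/s.

    Per track: agility = 1 / mean(m * dt over the phase's included points);
    population value is mean +/- SEM across tracks.  Tracks lacking the
    phase do not contribute; if no track has it the result is undefined
    (``n == 0``).
    """
    if not tracks:
        raise DataError("need at least one labeled track")
    values = []
    for tr in tracks:
        mask = (tr.labels == int(phase)) & tr.included
        if not mask.any():
            continue
        values.append(1.0 / float(tr.dwell_times[mask].mean()))
    return _population(values)


def agility_ratio(tracks: list[PhaseLabeledTrack]) -> PopulationStat:
    """Per-track crawl/reorientation agility ratio, averaged across tracks."""
    if not tracks:
        raise DataError("need at least one labeled track")
    values = []
    for tr in tracks:
        crawl_mask = (tr.labels == int(Phase.CRAWL)) & tr.included
        reo_mask = (tr.labels == int(Phase.REORIENT)) & tr.included
        if not (crawl_mask.any() and reo_mask.any()):
            continue
        values.append(
            float(tr.dwell_times[reo_mask].mean())
            / float(tr.dwell_times[crawl_mask].mean())
        )
    return _population(values)


# ---------------------------------------------------------------------------
# reorientation-turn sigma (Grubbs-cleaned Gaussian)


def _grubbs_critical(n: int, alpha: float = _GRUBBS_ALPHA) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_filter(values: np.ndarray, alpha: float = _GRUBBS_ALPHA) -> np.ndarray:
    """Boolean mask of values kept after iterative two-sided Grubbs removal."""
    v = np.asarray(values, dtype=float)
    keep = np.ones(len(v), dtype=bool)
    while keep.sum() >= 3:
        sample = v[keep]
        mean = sample.mean()
        sd = sample.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sample - mean)
        k = int(np.argmax(dev))
        if dev[k] / sd > _grubbs_critical(len(sample), alpha):
            keep[np.flatnonzero(keep)[k]] = False
        else:
            break
    return keep


def fit_reorientation_turn_sigma(
    angles: np.ndarray, alpha: float = _GRUBBS_ALPHA
) -> float:
    """Gaussian sigma of reorientation turns after Grubbs outlier removal.

    The event samples are few, so maximum likelihood alone would be swayed
    by individual outliers; iterative two-sided Grubbs screening (alpha =
    0.05) removes them before the sigma is taken from the survivors.
    """
    a = np.asarray(angles, dtype=float)
    if len(a) < 5:
        raise DataError(f"need at least 5 reorientation turns (got {len(a)})")
    keep = grubbs_filter(a, alpha)
    if keep.sum() < 5:
        raise NumericalError("fewer than 5 turns survive Grubbs filtering")
    return float(a[keep].std(ddof=1))


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class ExtractionResult:
    """Everything the analysis pipeline produces for one strain."""

    params: CrawlParameters
    fit_reports: dict[str, FitReport | None]
    labeled_tracks: list[PhaseLabeledTrack]
    frequency: PopulationStat
    crawl_agility: PopulationStat
    reorient_agility: PopulationStat
    warnings: list[str] = field(default_factory=list)

    def per_track_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.labeled_tracks:
            incl = tr.included
            reo = (tr.labels == int(Phase.REORIENT)) & incl
            crawl = (tr.labels == int(Phase.CRAWL)) & incl
            rows.append(
                {
                    "track_id": tr.track_id,
                    "n_smoothed_points": len(tr),
                    "n_rest_excluded": int(tr.rest_excluded.sum()),
                    "n_reorient": int(reo.sum()),
                    "reorientation_frequency": (
                        float(reo.sum() / incl.sum()) if incl.any() else float("nan")
                    ),
                    "crawl_agility_per_s": (
                        1.0 / float(tr.dwell_times[crawl].mean())
                        if crawl.any()
                        else float("nan")
                    ),
                    "reorient_agility_per_s": (
                        1.0 / float(tr.dwell_times[reo].mean())
                        if reo.any()
                        else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows)


def _try_fit(samples: np.ndarray, family: str, warnings: list[str], what: str):
    try:
        return fit_distribution(samples, family)
    except (DataError, NumericalError) as exc:
        warnings.append(f"{what}: degenerate or unfittable ({exc})")
        return None


def extract_parameters(
    tracks: list[RawTrack], config: AnalysisConfig
) -> ExtractionResult:
    """Run the full pipeline: smooth, rest-filter, detect, fit everything.

    Stage errors are re-raised with the offending track named.  Fits that
    are degenerate on the given data (e.g. a single straight track has a
    constant dwell time) are flagged as ``None`` with a warning rather than
    aborting the pipeline.
    """
    if not tracks:
        raise DataError("extract_parameters: empty track collection")
    warnings: list[str] = []
    labeled: list[PhaseLabeledTrack] = []
    for raw in tracks:
        try:
            sm = smooth_track(raw, config)
            labeled.append(detect_reorientations(sm, config))
        except (DataError, NumericalError) as exc:
            raise type(exc)(f"track {raw.track_id!r}: {exc}") from exc

    crawl_dwells, reorient_dwells, steps, turn_list = [], [], [], []
    crawl_angles = []
    for tr in labeled:
        if tr.too_short:
            warnings.append(f"track {tr.track_id!r}: too short, labeled all CRAWL")
        crawl_mask = (tr.labels == int(Phase.CRAWL)) & tr.included
        reo_mask = (tr.labels == int(Phase.REORIENT)) & tr.included
        crawl_dwells.append(tr.dwell_times[crawl_mask])
        reorient_dwells.append(tr.dwell_times[reo_mask])
        steps.append(step_lengths(tr))
        crawl_angles.append(crawl_turning_angles(tr))
        turn_list.append(reorientation_turns(tr))
    crawl_dwells = np.concatenate(crawl_dwells) if crawl_dwells else np.empty(0)
    reorient_dwells = (
        np.concatenate(reorient_dwells) if reorient_dwells else np.empty(0)
    )
    steps = np.concatenate(steps) if steps else np.empty(0)
    crawl_angles = np.concatenate(crawl_angles) if crawl_angles else np.empty(0)
    turns = np.concatenate(turn_list) if turn_list else np.empty(0)

    freq = reorientation_frequency(labeled)
    crawl_gamma_fit = (
        _try_fit(crawl_dwells, "gamma", warnings, "crawl dwell Gamma")
        if len(crawl_dwells)
        else None
    )
    reorient_gamma_fit = (
        _try_fit(reorient_dwells, "gamma", warnings, "reorientation dwell Gamma")
        if len(reorient_dwells)
        else None
    )
    step_fit = (
        _try_fit(steps, "weibull", warnings, "step-length Weibull")
        if len(steps)
        else None
    )
    # crawl-angle sigma with the mean pinned at zero: crawling is unbiased
    crawl_sigma = (
        float(np.sqrt(np.mean(crawl_angles**2))) if len(crawl_angles) else None
    )
    try:
        reorient_sigma = (
            fit_reorientation_turn_sigma(turns) if len(turns) >= 5 else None
        )
    except NumericalError as exc:
        warnings.append(f"reorientation turn sigma: {exc}")
        reorient_sigma = None
    if reorient_sigma is None:
        warnings.append("reorientation turn sigma: too few events to fit")

    def _pair(report, names):
        return (
            (report.params[names[0]], report.params[names[1]])
            if report is not None
            else None
        )

    params = CrawlParameters(
        reorientation_frequency=freq.mean if freq.defined else 0.0,
        crawl_time_gamma=_pair(crawl_gamma_fit, ("a", "scale")),
        reorient_time_gamma=_pair(reorient_gamma_fit, ("a", "scale")),
        step_weibull=_pair(step_fit, ("c", "scale")),
        crawl_angle_sigma=crawl_sigma,
        reorient_angle_sigma=reorient_sigma,
    )
    return ExtractionResult(
        params=params,
        fit_reports={
            "crawl_time_gamma": crawl_gamma_fit,
            "reorient_time_gamma": reorient_gamma_fit,
            "step_weibull": step_fit,
        },
        labeled_tracks=labeled,
        frequency=freq,
        crawl_agility=agility(labeled, Phase.CRAWL),
        reorient_agility=agility(labeled, Phase.REORIENT),
        warnings=warnings,
    )
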
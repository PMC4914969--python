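import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bprw import (
    AnalysisConfig,
    DataError,
    NumericalError,
    Phase,
    RawTrack,
    agility,
    agility_ratio,
    extract_parameters,
    fit_distribution,
    fit_reorientation_turn_sigma,
    reorientation_frequency,
    select_best,
    step_lengths,
    turning_angles,
)
from bprw.detection import PhaseLabeledTrack
from bprw.phase_stats import crawl_turning_angles, reorientation_turns


def make_labeled(xy, m=None, labels=None, excluded=None, dt=2.0):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    m = np.ones(n, dtype=int) if m is None else np.asarray(m)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)
    excluded = (
        np.zeros(n, dtype=bool) if excluded is None else np.asarray(excluded, dtype=bool)
    )
    return PhaseLabeledTrack("t", dt, xy, m, labels, excluded)


class TestTurningAngles:
    def test_collinear_motion_has_zero_angles(self):
        xy = np.column_stack([np.arange(6), np.zeros(6)])
        np.testing.assert_allclose(turning_angles(xy), 0.0)

    def test_ccw_square_gives_plus_half_pi(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0], [1, 0]], dtype=float)
        np.testing.assert_allclose(turning_angles(xy), np.pi / 2)

    def test_right_turn_sign_follows_cross_product(self):
        left = turning_angles(np.array([[0, 0], [1, 0], [1, 1.0]]))
        right = turning_angles(np.array([[0, 0], [1, 0], [1, -1.0]]))
        np.testing.assert_allclose(left, [np.pi / 2])
        np.testing.assert_allclose(right, [-np.pi / 2])

    def test_stride_subsamples_the_track(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0], [1, 0], [1, 1]], float)
        coarse = turning_angles(xy, stride=2)
        assert len(coarse) == 2
        np.testing.assert_allclose(np.abs(coarse), np.pi)

    def test_zero_displacement_skipped_and_counted(self):
        xy = np.array([[0, 0], [1, 0], [1, 0], [2, 1.0]])
        angles, skipped = turning_angles(xy, return_skipped=True)
        assert skipped == 2
        assert len(angles) == 0

    def test_reflection_negates_angles(self):
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.standard_normal((30, 2)), axis=0)
        mirrored = xy * np.array([1.0, -1.0])
        np.testing.assert_allclose(
            turning_angles(mirrored), -turning_angles(xy), atol=1e-12
        )

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(2)
        xy = np.cumsum(rng.standard_normal((30, 2)), axis=0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ R.T + [10.0, -4.0]
        np.testing.assert_allclose(
            turning_angles(moved), turning_angles(xy), atol=1e-12
        )


class TestStepsAndSegments:
    def test_two_crawl_points_one_step(self):
        tr = make_labeled([[0, 0], [1.5, 0]])
        np.testing.assert_allclose(step_lengths(tr), [1.5])

    def test_no_step_spans_a_reorientation(self):
        tr = make_labeled(
            [[0, 0], [1, 0], [2, 0], [3, 0]], labels=[0, 1, 0, 0]
        )
        np.testing.assert_allclose(step_lengths(tr), [1.0])  # only 2->3

    def test_no_step_spans_a_rest_exclusion(self):
        tr = make_labeled(
            [[0, 0], [1, 0], [2, 0], [3, 0]], excluded=[False, False, True, False]
        )
        np.testing.assert_allclose(step_lengths(tr), [1.0])  # only 0->1

    def test_weibull_mean_closed_form(self):
        rng = np.random.default_rng(9)
        k, lam = 1.5, 0.5
        steps = lam * rng.weibull(k, 4000)
        xy = np.zeros((4001, 2))
        xy[1:, 0] = np.cumsum(steps)
        got = step_lengths(make_labeled(xy)).mean()
        expected = lam * math.gamma(1 + 1 / k)
        assert got == pytest.approx(expected, rel=0.03)

    def test_reorientation_turn_is_across_the_event(self):
        # crawl in +x, reorient, crawl out at +90 degrees
        tr = make_labeled(
            [[0, 0], [1, 0], [2, 0], [2, 1], [2, 2]], labels=[0, 0, 1, 0, 0]
        )
        np.testing.assert_allclose(reorientation_turns(tr), [np.pi / 2])

    def test_crawl_angles_exclude_reorientation_vertices(self):
        tr = make_labeled(
            [[0, 0], [1, 0], [2, 0], [2, 1], [2, 2], [2, 3]],
            labels=[0, 0, 1, 0, 0, 0],
        )
        np.testing.assert_allclose(crawl_turning_angles(tr), [0.0])  # 3-4-5 only


class TestFitting:
    def test_weibull_recovery_and_selection(self):
        rng = np.random.default_rng(21)
        x = 0.5 * rng.weibull(1.5, 10_000)
        best, _ = select_best(x)
        assert best.family == "weibull"
        assert best.params["c"] == pytest.approx(1.5, rel=0.05)
        assert best.params["scale"] == pytest.approx(0.5, rel=0.05)

    def test_normal_recovery_and_selection(self):
        rng = np.random.default_rng(22)
        x = rng.normal(0.0, 0.3, 10_000)
        best, _ = select_best(x)
        assert best.family == "normal"
        assert best.params["scale"] == pytest.approx(0.3, rel=0.05)

    def test_gamma_recovery(self):
        rng = np.random.default_rng(23)
        x = rng.gamma(4.0, 5.0, 10_000)
        rep = fit_distribution(x, "gamma")
        assert rep.params["a"] == pytest.approx(4.0, rel=0.1)
        assert rep.params["scale"] == pytest.approx(5.0, rel=0.1)
        assert rep.stderr["a"] is not None and rep.stderr["a"] < 0.2

    def test_selection_consistency_across_repeats(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            best, _ = select_best(0.5 * rng.weibull(1.5, 10_000))
            hits += best.family == "weibull"
        assert hits >= 10 * 0.95 - 1e-9

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(NumericalError, match="degenerate"):
            fit_distribution(np.full(50, 3.0), "normal")

    def test_positive_family_rejects_negative_samples(self):
        with pytest.raises(DataError, match="positive"):
            fit_distribution(np.linspace(-1, 1, 50), "weibull")

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError, match="20"):
            fit_distribution(np.arange(10.0), "normal")


class TestPopulationStats:
    def test_frequency_arithmetic(self):
        tr = make_labeled(np.zeros((4, 2)), labels=[0, 0, 1, 0])
        assert reorientation_frequency([tr]).mean == pytest.approx(0.25)

    def test_all_crawl_gives_zero(self):
        tr = make_labeled(np.zeros((5, 2)))
        assert reorientation_frequency([tr]).mean == 0.0

    def test_frequency_excludes_rest_points(self):
        tr = make_labeled(
            np.zeros((5, 2)), labels=[0, 1, 0, 0, 0], excluded=[0, 0, 0, 1, 1]
        )
        assert reorientation_frequency([tr]).mean == pytest.approx(1 / 3)

    def test_agility_arithmetic(self):
        tr = make_labeled(np.zeros((3, 2)), m=[1, 2, 3], dt=2.0)
        assert agility([tr], Phase.CRAWL).mean == pytest.approx(0.25)

    def test_agility_upper_bound_at_dt(self):
        tr = make_labeled(np.zeros((5, 2)), dt=2.0)
        assert agility([tr], Phase.CRAWL).mean == pytest.approx(0.5)

    def test_absent_phase_is_undefined(self):
        tr = make_labeled(np.zeros((5, 2)))
        stat = agility([tr], Phase.REORIENT)
        assert not stat.defined

    def test_agility_ratio_matches_dwell_ratio(self):
        tr = make_labeled(
            np.zeros((4, 2)), m=[1, 1, 10, 1], labels=[0, 0, 1, 0], dt=2.0
        )
        assert agility_ratio([tr]).mean == pytest.approx(10.0)

    def test_simulated_gamma_dwell_agility(self):
        rng = np.random.default_rng(4)
        m = np.rint(rng.gamma(16.0, 0.25, 2000) / 2.0).clip(min=1).astype(int)
        tr = make_labeled(np.zeros((len(m), 2)), m=m, dt=2.0)
        assert agility([tr], Phase.CRAWL).mean == pytest.approx(
            1.0 / (m.mean() * 2.0), rel=1e-12
        )


class TestReorientationSigma:
    def test_identical_angles_give_zero_sigma(self):
        assert fit_reorientation_turn_sigma(np.full(8, 0.7)) == 0.0

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(12)
        angles = rng.normal(0.0, 1.0, 200)
        spiked = np.append(angles, 10.0)
        assert fit_reorientation_turn_sigma(spiked) == pytest.approx(1.0, rel=0.1)

    def test_uniform_angles_give_pi_over_sqrt3(self):
        rng = np.random.default_rng(13)
        angles = rng.uniform(-np.pi, np.pi, 5000)
        assert fit_reorientation_turn_sigma(angles) == pytest.approx(
            np.pi / np.sqrt(3), rel=0.05
        )

    def test_too_few_angles_rejected(self):
        with pytest.raises(DataError):
            fit_reorientation_turn_sigma(np.array([0.1, 0.2, 0.3]))


class TestExtractParameters:
    def test_empty_collection_rejected(self):
        with pytest.raises(DataError):
            extract_parameters([], AnalysisConfig())

    def test_single_straight_track_is_degenerate_but_survives(self):
        xy = np.column_stack([np.arange(50) * 1.0, np.zeros(50)])
        res = extract_parameters(
            [RawTrack("s", 2.0, xy)], AnalysisConfig(resolution_limit_r=0.5)
        )
        assert res.params.reorientation_frequency == 0.0
        assert res.params.crawl_angle_sigma == pytest.approx(0.0, abs=1e-12)
        assert res.params.crawl_time_gamma is None  # constant dwell, flagged
        assert any("degenerate" in w or "too few" in w for w in res.warnings)
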
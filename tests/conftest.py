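import numpy as np
import pytest

from bprw import AnalysisConfig, CrawlParameters, SimulationConfig

# Study conditions used throughout the closed-loop tests: a strain-like
# phenotype, rendered at a resolution fine enough that consecutive model
# points stay separable (P(step <= 1.5 r) ~ 1%).
RENDER_R = 0.015  # mm
TRUE_PARAMS = CrawlParameters(
    reorientation_frequency=0.10,
    crawl_time_gamma=(16.0, 0.25),  # mean 4 s, regular peristaltic progress
    reorient_time_gamma=(4.0, 5.0),  # mean 20 s, broad long-tailed pauses
    step_weibull=(1.5, 0.5),  # mm
    crawl_angle_sigma=0.3,  # rad
    reorient_angle_sigma=1.2,  # rad
)


@pytest.fixture(scope="session")
def true_params() -> CrawlParameters:
    return TRUE_PARAMS


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    # rest filter disabled: the generator models no resting pathology, and
    # a 14 s cutoff would censor genuine 20 s-scale reorientation dwells
    return AnalysisConfig(
        resolution_limit_r=RENDER_R, rest_threshold=float("inf"), dt=2.0
    )


def make_sim_config(**overrides) -> SimulationConfig:
    defaults = dict(n_tracks=25, duration=1800.0, dt=2.0, seed=0, r=RENDER_R)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def simulated_population(true_params):
    """25 rendered tracks of 30 simulated minutes at the true phenotype."""
    from bprw import simulate_population

    return simulate_population(true_params, make_sim_config(seed=11))


@pytest.fixture(scope="session")
def labeled_population(simulated_population, analysis_config):
    from bprw import detect_reorientations, smooth_track

    return [
        detect_reorientations(smooth_track(t, analysis_config), analysis_config)
        for t in simulated_population
    ]
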
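import pytest

from wormamp.lineage_tracking import TrackerConfig, track_experiment
from wormamp.trench_sim import SimulationParams, simulate_experiment


def noevict_params(seed: int, **overrides) -> SimulationParams:
    """A configuration in which the trench never fills during the movie, so
    every division and lysis is individually visible at frame resolution
    (no evictions, no hidden open-end events)."""
    kw = dict(seed=seed, obs_noise_sd=0.0, lambda0=0.05, lambda_treat=0.2,
              trench_len=300.0, t_total=150.0, treat_start=60.0,
              treat_end=120.0, n_trenches=6)
    kw.update(overrides)
    return SimulationParams(**kw)


@pytest.fixture(scope="session")
def noevict_run():
    """Noise-free no-eviction simulation plus tracked output."""
    params = noevict_params(seed=2)
    obs, truth = simulate_experiment(params)
    lineage, assignments = track_experiment(obs, TrackerConfig.from_params(params))
    return params, obs, truth, lineage, assignments


@pytest.fixture(scope="session")
def default_noisefree_run():
    """Noise-free, lysis-free run with the study device geometry
    (75 um trench, 1 min frames, treatment 90-270 min): divisions,
    evictions and censoring."""
    params = SimulationParams(seed=3, obs_noise_sd=0.0, lambda0=0.0,
                              lambda_treat=0.0, n_trenches=5, t_total=300.0,
                              treat_end=270.0)
    obs, truth = simulate_experiment(params)
    lineage, assignments = track_experiment(obs, TrackerConfig.from_params(params))
    return params, obs, truth, lineage, assignments
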
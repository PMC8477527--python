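"""Shared fixtures: synthetic datasets at the study's design scale.

The expensive full-budget fit is session-scoped so descriptive checks, the
headline-model check and the model-vs-sample sanity check all share it.
"""

import pytest

from hurdlema import (
    SamplerConfig,
    SimulationDesign,
    fit,
    simulate_dataset,
    summarize_posterior,
)

#: master seed for the study-scale fixtures (fixed once for reproducibility)
SEED = 20210927


@pytest.fixture(scope="session")
def study_design():
    """Default design: 99 participants, 8 prompts x 3 days, ~14% missed."""
    return SimulationDesign(seed=SEED)


@pytest.fixture(scope="session")
def study_dataset(study_design):
    data, truth = simulate_dataset(study_design)
    return data, truth


@pytest.fixture(scope="session")
def study_fit(study_design, study_dataset):
    """Intercept-only fit at the default 4x2000 budget (shared, ~2 min)."""
    data, truth = study_dataset
    draws = fit(data, study_design.spec,
                SamplerConfig(n_chains=4, n_iter=2000, seed=SEED))
    return draws, summarize_posterior(draws)


@pytest.fixture()
def tiny_design():
    return SimulationDesign(n_participants=8, prompts_per_day=4, n_days=2,
                            missingness=0.1, seed=42)


@pytest.fixture()
def tiny_dataset(tiny_design):
    return simulate_dataset(tiny_design)
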
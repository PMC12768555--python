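"""Shared fixtures.

The calibration fits at the study's cohort size (10,000 simulated
participants per regime) are expensive, so they are computed once per
session and shared between the unit tests that need fitted hypothesis
models and the acceptance checks.
"""

import numpy as np
import pytest

from pluralcue.bayes import MCMCConfig, fit_beta_regression
from pluralcue.lexicon import load_lexicon, toy_lexicon_path
from pluralcue.simulate import hypothesis_spec, simulate_cohort

CALIBRATION_N = 10_000
CALIBRATION_SEED = 2024


@pytest.fixture(scope="session")
def toy_lexicon():
    return load_lexicon(toy_lexicon_path())


def _fit(hyp: str, design: str, seed_offset: int):
    spec = hypothesis_spec(hyp, design=design)
    cohort = simulate_cohort(spec, CALIBRATION_N, CALIBRATION_SEED + seed_offset)
    return fit_beta_regression(
        cohort, mcmc=MCMCConfig(seed=seed_offset), hypothesis=hyp
    )


@pytest.fixture(scope="session")
def fixed_design_posteriors():
    """h0/h1/h2 models fitted to fixed-gender-design calibration cohorts."""
    return {
        "h0": _fit("h0", "fixed", 0),
        "h1": _fit("h1", "fixed", 1),
        "h2": _fit("h2", "fixed", 2),
    }


@pytest.fixture(scope="session")
def sampled_design_h1_posterior():
    """h1 model fitted to a sampled-gender-design calibration cohort."""
    return _fit("h1", "sampled", 3)


@pytest.fixture(scope="session")
def light_mcmc():
    """A cheaper sampler configuration for small-cohort fits in tests."""
    return MCMCConfig(n_walkers=16, n_steps=500, n_warmup=500, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
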
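import numpy as np
import pytest

import oscphase as op
from oscphase import model, scoring


def tiny_config(**overrides) -> op.SimulationConfig:
    """A small experiment for fast pipeline tests."""
    defaults = dict(
        n_participants=2,
        sessions=1,
        reps_per_condition=1,
        seed=7,
    )
    defaults.update(overrides)
    return op.SimulationConfig(**defaults)


#: Reduced schedule for unit tests that only need a valid posterior.
TEST_PROFILE = model.McmcSettings(chains=2, burn_in=400, draws=800, thin=1)


def outcomes_from_generator(config: op.SimulationConfig):
    """Cycle-level outcome table scored at the default tolerance."""
    cyc = op.simulate_cycle_outcomes(config)
    out = scoring.pool_factors(cyc)
    correct = np.array(
        [
            scoring.classify_cycle(ph, instr)
            for ph, instr in zip(out["relative_phase"], out["instruction"])
        ]
    )
    return out.assign(correct=correct)


@pytest.fixture(scope="session")
def default_fit():
    """One full-size generator run fitted with the scaled MCMC profile.

    Shared across tests that need a converged posterior on data generated
    under the default effect sizes.
    """
    config = op.SimulationConfig(seed=2024)
    out = outcomes_from_generator(config)
    X, y, part = model.build_design(out)
    post, diag = model.fit_model(
        X, y, part, settings=model.SCALED_PROFILE, seed=5
    )
    return config, out, post, diag
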
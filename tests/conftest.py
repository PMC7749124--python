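import pytest
from hypothesis import settings

import pinegrowth as pg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design():
    return pg.design_experiment(pg.DesignConfig(seed=11))


@pytest.fixture(scope="session")
def field_sim_wide(default_design):
    """One field-sized simulated measurement table (64 trees, field-like truth)."""
    return pg.simulate_measurements(default_design, pg.EffectConfig.field_calibrated(), seed=12)


@pytest.fixture(scope="session")
def field_sim_table(field_sim_wide):
    return pg.compute_increments(field_sim_wide)
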
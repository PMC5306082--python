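"""Shared fixtures: packaged configurations, models and the four
headline simulations (both species at 0.05 and 300 mg/kg bw, 720 h),
plus the two full sensitivity screens.  Session-scoped because the
simulations are deterministic and reused by many tests."""

import pytest

from myripbk import packaged_config, sensitivity_screen


@pytest.fixture(scope="session")
def rat_config():
    return packaged_config("rat")


@pytest.fixture(scope="session")
def human_config():
    return packaged_config("human")


@pytest.fixture(scope="session")
def rat_model(rat_config):
    return rat_config.build_model()


@pytest.fixture(scope="session")
def human_model(human_config):
    return human_config.build_model()


@pytest.fixture(scope="session")
def sims(rat_model, human_model):
    """(species, dose mg/kg) -> 720 h SimulationResult."""
    models = {"rat": rat_model, "human": human_model}
    return {
        (sp, dose): models[sp].simulate(dose)
        for sp in ("rat", "human")
        for dose in (0.05, 300.0)
    }


@pytest.fixture(scope="session")
def screens(rat_config, human_config):
    """Full normalized-sensitivity screens at 0.05 mg/kg bw."""
    return {
        "rat": sensitivity_screen(rat_config),
        "human": sensitivity_screen(human_config),
    }
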
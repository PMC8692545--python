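import pytest

import isoarctic as ia


@pytest.fixture(scope="session")
def reanalysis_traj():
    """Default calibrated historical run, 1970-2019."""
    return ia.run(ia.build_scenario("reanalysis"))


@pytest.fixture(scope="session")
def emissions_traj():
    """Default calibrated strong-warming run, 1850-2100."""
    return ia.run(ia.build_scenario("emissions"))


@pytest.fixture(scope="session")
def control_traj():
    """Preindustrial control run (flat drivers + deterministic oscillation)."""
    return ia.run(ia.build_scenario("control"), spinup_years=100)
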
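import pytest

from pestnatal.experiments import build_study_frame
from pestnatal.synth import GridSpec, SimConfig, build_panel, generate_applications, \
    generate_births

SEED = 20251


@pytest.fixture(scope="session")
def grid():
    return GridSpec(3, 3)


@pytest.fixture(scope="session")
def sim_cfg():
    # four birth years including a missing-tobacco year, modest cohort
    return SimConfig(seed=SEED, years=(2004, 2007), n_births_per_year=1500,
                     missing_tobacco_year=2006)


@pytest.fixture(scope="session")
def applications(grid, sim_cfg):
    return generate_applications(grid, sim_cfg)


@pytest.fixture(scope="session")
def panel(grid, sim_cfg, applications):
    return build_panel(applications, grid, sim_cfg)


@pytest.fixture(scope="session")
def births(grid, sim_cfg, panel):
    return generate_births(grid, sim_cfg, panel)


@pytest.fixture(scope="session")
def study(grid, sim_cfg):
    """Analysis-ready frame with exposures, indicators and sample labels."""
    frame, cutoffs, log, apps = build_study_frame(grid, sim_cfg)
    return {"frame": frame, "cutoffs": cutoffs, "log": log, "apps": apps}
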
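import pytest

from shs_hia import HIAModel, SimulationConfig, germany, synthetic_data
from shs_hia.model_io import Scenario


@pytest.fixture(scope="session")
def study_fixture():
    """Default synthetic study setup: 2014-2040, published risk inputs."""
    return synthetic_data.generate_full_study_fixture(seed=123)


@pytest.fixture(scope="session")
def det_results(study_fixture):
    """Deterministic-mode results for all three scenarios (noise-free)."""
    fx = study_fixture
    model = HIAModel(fx.population, fx.disease_inputs, fx.exposure, fx.rr,
                     fx.config)
    return model.run(engine_mode="deterministic")


@pytest.fixture(scope="session")
def micro_results(study_fixture):
    """Micro-mode results at the study's 10,000-individual sample size."""
    fx = study_fixture
    model = HIAModel(fx.population, fx.disease_inputs, fx.exposure, fx.rr,
                     fx.config)
    return model.run(engine_mode="micro")


@pytest.fixture()
def short_config():
    """Three-year deterministic run for cheap structural checks."""
    return SimulationConfig(start_year=2014, end_year=2016,
                            n_individuals=1000, rng_seed=5,
                            scenarios=(Scenario("reference", 0.0, 2014),),
                            engine_mode="deterministic")


@pytest.fixture(scope="session")
def published_exposure():
    return germany.exposure_group_table()


@pytest.fixture(scope="session")
def published_rr():
    return germany.relative_risk_table()
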
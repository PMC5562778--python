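import pytest
from hypothesis import HealthCheck, settings

from estragole_pbk import build_model_spec, load_population, simulate
from estragole_pbk.interethnic_risk import dose_response_sweep

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chinese_config():
    return load_population("chinese")


@pytest.fixture(scope="session")
def caucasian_config():
    return load_population("caucasian")


@pytest.fixture(scope="session")
def chinese_spec(chinese_config):
    return build_model_spec(chinese_config)


@pytest.fixture(scope="session")
def caucasian_spec(caucasian_config):
    return build_model_spec(caucasian_config)


@pytest.fixture(scope="session")
def low_dose_results(chinese_spec, caucasian_spec):
    """24-h simulations at the dietary-intake dose of 0.01 mg/kg bw."""
    return {
        "chinese": simulate(chinese_spec, 0.01),
        "caucasian": simulate(caucasian_spec, 0.01),
    }


@pytest.fixture(scope="session")
def dose_tables(chinese_spec, caucasian_spec):
    """Dose-response tables at the three benchmark doses for both populations."""
    doses = [0.01, 5.0, 150.0]
    return {
        "chinese": dose_response_sweep(chinese_spec, doses, population="chinese"),
        "caucasian": dose_response_sweep(caucasian_spec, doses, population="caucasian"),
    }
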
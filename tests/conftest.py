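import pytest
from hypothesis import settings

from tnfi_bia import load_poland, load_poland_reported_costs, study_config, run_pipeline
from tnfi_bia.synth import MarketScenarioConfig, generate_series

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def poland():
    """The packaged Polish NHF 2013-2021 record set."""
    return load_poland()


@pytest.fixture(scope="session")
def reported_costs():
    """Published per-mg / per-patient treatment costs (independent payer source)."""
    return load_poland_reported_costs()


@pytest.fixture(scope="session")
def bundle():
    """One full pipeline run under the study configuration."""
    return run_pipeline(study_config())


@pytest.fixture()
def clean_config():
    """Noise-free synthetic market mirroring the infliximab trajectory."""
    return MarketScenarioConfig(noise_cv=0.0, seed=7)


@pytest.fixture()
def clean_series(clean_config):
    rs = generate_series(clean_config)
    return [r for r in rs.records]
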
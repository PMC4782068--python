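import pytest

from fallowcarbon import (AnalysisConfig, GeneratorConfig, all_site_pools,
                          generate_inventory)


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def inventory():
    """Default synthetic 25-site inventory, fixed seed."""
    return generate_inventory(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def pools(inventory, analysis_config):
    return all_site_pools(inventory, analysis_config)
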
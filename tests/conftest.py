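import pytest

from crossregnet import (
    GeneratorConfig,
    build_network,
    generate_bundle,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(default_config):
    return generate_bundle(default_config)


@pytest.fixture(scope="session")
def network(bundle, default_config):
    return build_network(
        bundle.genes,
        bundle.sf_hits,
        bundle.tf_hits,
        dataset=default_config.dataset,
    )
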
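import pytest

from evseek.simulate import generate_bundle


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Default synthetic study: 100 genes, 8 tissues, 5 planted markers at fold 4."""
    return generate_bundle(seed=1)
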
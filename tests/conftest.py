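import pytest

from needlesense import bnn, phantom, remap


@pytest.fixture(scope="session")
def table():
    return remap.default_remap_table()


@pytest.fixture(scope="session")
def templates(table):
    return phantom.default_templates(table)


@pytest.fixture(scope="session")
def train_dataset(templates):
    return phantom.generate_dataset(templates, seed=1)


@pytest.fixture(scope="session")
def train_features(train_dataset, table):
    return phantom.remap_features(train_dataset, table)


@pytest.fixture(scope="session")
def _trained(train_features):
    x, y = train_features
    return bnn.train(x, y, bnn.BNNConfig(seed=3))


@pytest.fixture(scope="session")
def trained_model(_trained):
    return _trained[0]


@pytest.fixture(scope="session")
def cost_trace(_trained):
    return _trained[1]


@pytest.fixture(scope="session")
def test_dataset(templates):
    return phantom.generate_dataset(templates, seed=99)
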
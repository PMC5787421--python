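import numpy as np
import pytest

from coxen import ExpressionMatrix, SyntheticConfig, generate


def make_expr(values, label="test", gene_prefix="G", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default synthetic study conditions, shared."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A default dataset written to disk in the TSV dialects."""
    from coxen import write_fixture
    d = tmp_path_factory.mktemp("fixture")
    ds = generate(SyntheticConfig(seed=11))
    write_fixture(ds, d)
    return d
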
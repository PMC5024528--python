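import numpy as np
import pytest

from morphodtt import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across read-only tests."""
    return synthetic.generate_study(seed=42)


@pytest.fixture(scope="session")
def study_bundle(study, tmp_path_factory):
    """The same study written to disk as a pipeline-ready bundle."""
    out = tmp_path_factory.mktemp("bundle")
    return study.write(out)


def random_shapes(rng, n, k):
    """Independent random configurations (no phylogenetic structure)."""
    base = synthetic.reference_skull(k)
    return np.stack([base + rng.normal(0, 0.03, (k, 2)) for _ in range(n)])
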
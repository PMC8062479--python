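import numpy as np
import pytest

from envcomplexity import Resource, build_hierarchical_scheme


@pytest.fixture(scope="session")
def tree32():
    """Hierarchical 63-environment scheme on 32 ranked resources."""
    resources = [Resource(i, f"cs{i + 1}", float(i + 1)) for i in range(32)]
    return build_hierarchical_scheme(resources, total_carbon=1.5)


@pytest.fixture(scope="session")
def tree8():
    resources = [Resource(i, f"cs{i + 1}", float(i + 1)) for i in range(8)]
    return build_hierarchical_scheme(resources, total_carbon=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
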
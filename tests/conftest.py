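import numpy as np
import pytest

from fusemble import ClassRegistry, GeneratorConfig, PredictionSet, generate


@pytest.fixture(scope="session")
def registry4():
    return ClassRegistry(["BLT", "LCY", "MLC", "PLC"])


@pytest.fixture(scope="session")
def synth_default():
    """The default 16-member synthetic bank at seed 7 (shared: read-only)."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture
def random_ps_factory():
    """Factory for small random prediction sets with valid probabilities."""

    def make(seed, m=3, n=20, c=4):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(c), size=(m, n))
        truth = rng.integers(0, c, size=n)
        return PredictionSet(
            classifiers=[f"clf{j}" for j in range(m)],
            probs=probs,
            truth=truth,
            registry=ClassRegistry([f"C{i}" for i in range(c)]),
        )

    return make
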
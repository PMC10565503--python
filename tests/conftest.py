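import numpy as np
import pytest

from zolekpd.io import load_population_parameters
from zolekpd.synthetic import GeneratorConfig, default_designs, generate


@pytest.fixture(scope="session")
def pop():
    """Published population model (typical values, omega2, sigma2)."""
    return load_population_parameters()


@pytest.fixture(scope="session")
def params(pop):
    """Typical structural parameters at the largest trial's baseline."""
    return pop.theta.replace(base=0.79)


@pytest.fixture(scope="session")
def small_dataset(pop):
    """Ten synthetic arms (the bundled trial designs) at the published values."""
    return generate(GeneratorConfig(pop=pop, designs=tuple(default_designs()),
                                    seed=42))


@pytest.fixture(scope="session")
def monthly_grid():
    return np.arange(0.0, 72.0 + 1e-9, 1.0)
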
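import warnings

import numpy as np
import pytest

from eiflux.pm import PMState
from eiflux.synthetic import SynthConfig, generate_site

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


def random_states(n: int, seed: int = 0) -> PMState:
    """Random but physically valid PM states spanning the tower envelope.

    Humidity is drawn as RH in [25, 98] % so VPD stays below saturation;
    super-saturated or desert-dry wet-canopy states have no quadratic
    solution and are not valid inputs.
    """
    rng = np.random.default_rng(seed)
    ta = rng.uniform(0.0, 40.0, n)
    esat = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))
    rh = rng.uniform(25.0, 98.0, n)
    return PMState(
        ta=ta,
        vpd=esat * (1.0 - rh / 100.0),
        available_energy=rng.uniform(-50.0, 800.0, n),
        ra=rng.uniform(5.0, 200.0, n),
    )


@pytest.fixture(scope="session")
def small_site():
    """One synthetic site-year with moderate noise (shared, read-only)."""
    return generate_site(SynthConfig(years=1, seed=42, noise_sd=10.0))
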
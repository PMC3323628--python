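import numpy as np
import pytest

from promothermo import TwoActivatorSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_systems(rng, n, dose_range=(1e-3, 1e3), factor_range=(1e-2, 1e2)):
    """Log-uniform random two-activator systems (doses and all four factors)."""
    lo_d, hi_d = np.log(dose_range)
    lo_f, hi_f = np.log(factor_range)
    for _ in range(n):
        x_p, x_a, x_b = np.exp(rng.uniform(lo_d, hi_d, 3))
        w_a, w_b, om, om3 = np.exp(rng.uniform(lo_f, hi_f, 4))
        yield TwoActivatorSystem(x_p, x_a, x_b, w_a, w_b, om, om3)
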
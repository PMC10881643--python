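import numpy as np
import pytest

from sflt1kin import ParameterSet, Protocol


@pytest.fixture
def params():
    """A generic well-behaved parameter set."""
    return ParameterSet(k_prod=1000.0, tau=0.5, k_out_Si=0.5, k_deg_Si=0.5,
                        k_deg_Sx=0.1)


@pytest.fixture
def accumulation_proto():
    return Protocol(kind="accumulation", horizon=48.0, media_events=[0.0],
                    history="steady_state")


def random_parameter_sets(n, seed=0, rate_range=(1e-3, 10.0), tau_range=(0.0, 4.0)):
    """Log-uniform rate draws used by the engine-equivalence checks."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log(rate_range[0]), np.log(rate_range[1])
    out = []
    for _ in range(n):
        r = np.exp(rng.uniform(lo, hi, size=3))
        out.append(ParameterSet(
            k_prod=float(np.exp(rng.uniform(np.log(10), np.log(1e5)))),
            tau=float(rng.uniform(*tau_range)),
            k_out_Si=float(r[0]), k_deg_Si=float(r[1]), k_deg_Sx=float(r[2]),
        ))
    return out
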
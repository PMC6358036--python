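import numpy as np
import pandas as pd
import pytest

from mrkit.data import HarmonizedInstrumentSet
from mrkit.simulate import SimulationConfig, simulate_two_sample


@pytest.fixture
def urate_like_study():
    """One seeded 30-instrument urate-like simulated study (null effect)."""
    return simulate_two_sample(SimulationConfig(seed=42))


@pytest.fixture
def instruments(urate_like_study):
    return urate_like_study.to_instrument_set()


def make_instruments(gamma, sigma_x, Gamma, sigma_y, **meta) -> HarmonizedInstrumentSet:
    """Hand-build an instrument set from plain arrays."""
    k = len(gamma)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(k)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "gamma_hat": np.asarray(gamma, dtype=float),
            "sigma_x": np.asarray(sigma_x, dtype=float),
            "Gamma_hat": np.asarray(Gamma, dtype=float),
            "sigma_y": np.asarray(sigma_y, dtype=float),
        }
    )
    return HarmonizedInstrumentSet(df, **meta)


@pytest.fixture
def toy_instruments():
    """Two instruments whose Wald ratios are 0.5 +- 0.2 and 0.3 +- 0.1.

    gamma = 1 with tiny sigma_x so the first-order delta SE equals
    sigma_y/gamma to high accuracy.
    """
    return make_instruments(
        gamma=[1.0, 1.0],
        sigma_x=[1e-12, 1e-12],
        Gamma=[0.5, 0.3],
        sigma_y=[0.2, 0.1],
    )
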
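import numpy as np
import pandas as pd
import pytest

from serinepkpd import (
    RandomEffectSpec,
    default_parameters,
    phase2_design,
    simulate_dataset,
)
from serinepkpd.params import ModelParameters
from serinepkpd.saem import SaemOptions


@pytest.fixture(scope="session")
def params():
    """Package default parameter set (final PD estimates + placeholder PK)."""
    return default_parameters()


@pytest.fixture(scope="session")
def noise_free_params(params):
    """Same structural model with all variability switched off."""
    return ModelParameters(
        pk=params.pk, pd=params.pd, ranef=RandomEffectSpec(0, 0, 0, 0, 0.0, 0.0)
    )


@pytest.fixture(scope="session")
def small_dataset(params):
    """A 40-subject phase-II-shaped trial for fast estimation tests."""
    return simulate_dataset(phase2_design(), params, n=40, seed=1234)


@pytest.fixture(scope="session")
def fast_saem():
    return SaemOptions(n_burn=80, n_smooth=40)


def make_demographics(ages, weights, arms, sexes=None):
    n = len(ages)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": ages,
            "weight": weights,
            "sex": sexes if sexes is not None else ["male"] * n,
            "arm": arms,
        }
    )
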
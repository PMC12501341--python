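import numpy as np
import pandas as pd
import pytest

from demrisk._util import FACTOR_LEVELS
from demrisk.weights import load_all_weight_tables


@pytest.fixture(scope="session")
def tables():
    return load_all_weight_tables()


def random_complete_profile(rng: np.random.Generator) -> pd.Series:
    """A fully populated harmonized profile with uniformly random levels."""
    prof = {
        "baseline_age": float(rng.uniform(40, 95)),
        "sex": rng.choice(["female", "male"]),
    }
    for factor, levels in FACTOR_LEVELS.items():
        if factor == "sex":
            continue
        prof[factor] = rng.choice(levels)
    return pd.Series(prof)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 400-participant synthetic cohort, fully observed."""
    from demrisk.synthetic import default_spec, generate_cohort

    return generate_cohort(default_spec(400, seed=11))
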
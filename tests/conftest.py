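import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from norse.registry import BiomarkerVector, validate_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(**cols) -> pd.DataFrame:
    """Minimal participant table; missing schema columns become NaN."""
    n = max(len(v) for v in cols.values() if hasattr(v, "__len__"))
    base = {
        "participant_id": np.arange(n),
        "sex": ["male"] * n,
        "age": [40.0] * n,
    }
    base.update(cols)
    return validate_table(pd.DataFrame(base))


def vector_from(values, name="B") -> BiomarkerVector:
    return BiomarkerVector(name=name, values=pd.Series(values, dtype=float))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def linear_cohort():
    """B ~ N(0, 1), prevalence P(%) = 10 + 4 B, n = 200,000.

    Direct binomial simulation, independent of the package's own
    population generator; the generating slope is the oracle.
    """
    gen = np.random.default_rng(777)
    n = 200_000
    b = gen.standard_normal(n)
    p = np.clip(10.0 + 4.0 * b, 0.0, 100.0) / 100.0
    flags = (gen.random(n) < p).astype(float)
    return pd.Series(b), pd.Series(flags)
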
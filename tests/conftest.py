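import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rankcutoff as rc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def micro_records():
    """The worked micro-example: values [0, 0, 0, 0, 10]."""
    return [rc.ValueRecord(f"g{i}", v) for i, v in enumerate([0, 0, 0, 0, 10], 1)]


@pytest.fixture
def micro_profile(micro_records):
    return rc.rank_profile(micro_records)


@pytest.fixture
def fixtures():
    return rc.degenerate_fixtures()


def random_profile(rng: np.random.Generator, n: int | None = None) -> rc.RankedProfile:
    """A random non-flat profile for invariance checks."""
    if n is None:
        n = int(rng.integers(5, 200))
    values = rng.gamma(0.5, 10.0, size=n)
    values[rng.integers(0, n)] += 100.0  # guarantee non-flat
    recs = [rc.ValueRecord(f"r{i:04d}", float(v)) for i, v in enumerate(values)]
    return rc.rank_profile(recs)
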
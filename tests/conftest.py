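import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from covisim.categories import (StimulusSet, gen_hybrid_categories,
                                gen_ii_categories)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ii_set() -> StimulusSet:
    """Standard 300+300 information-integration sample."""
    return gen_ii_categories(seed=42)


@pytest.fixture(scope="session")
def hybrid_set() -> StimulusSet:
    return gen_hybrid_categories(seed=42)


@pytest.fixture(scope="session")
def toy_separable() -> StimulusSet:
    """Tiny, perfectly separable two-cluster set (A left, B right)."""
    rng = np.random.default_rng(0)
    a = np.column_stack([rng.uniform(10, 25, 10), rng.uniform(40, 60, 10)])
    b = np.column_stack([rng.uniform(75, 90, 10), rng.uniform(40, 60, 10)])
    return StimulusSet(stimuli=np.vstack([a, b]),
                       labels=np.repeat([0, 1], 10),
                       structure_kind="RB", bound_spec="toy separable",
                       n_per_category=10)
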
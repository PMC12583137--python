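import numpy as np
import pytest

from triomics.benchmarks import default_benchmark_loci
from triomics.datatypes import ScenarioSpec
from triomics.simulate import simulate_cohort


@pytest.fixture(scope="session")
def causal_cohort():
    """Small causal cohort: 2 loci, 1 true mediator + 9 null transcripts each."""
    return simulate_cohort(
        500, default_benchmark_loci(2), ScenarioSpec(kind="causal"), seed=42
    )


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(
        500, default_benchmark_loci(2), ScenarioSpec(kind="null", beta_lg=0, beta_gt=0),
        seed=43,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
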
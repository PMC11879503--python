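import numpy as np
import pytest

from netpsych.ggm import WeightedNetwork
from netpsych.simulate import (
    STUDY_COMMUNITIES,
    PrecisionSpec,
    build_precision,
    sample_copula,
    table1_marginals,
)


def random_network(rng, p, density=0.5, communities=None):
    """A random sparse signed weighted network for oracle comparisons."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 0.6) * rng.choice([-1, 1])
    names = [f"n{i}" for i in range(p)]
    return WeightedNetwork(W, names, communities or {})


@pytest.fixture(scope="session")
def study_sample():
    """One moderate questionnaire-like sample with a known sparse structure."""
    edges = ((0, 1, 0.3), (2, 3, 0.25), (4, 5, 0.2), (0, 6, 0.2), (6, 7, 0.25))
    K = build_precision(PrecisionSpec(8, edges, 0.0))
    data = sample_copula(
        1000, K, table1_marginals(), seed=424242, communities=STUDY_COMMUNITIES
    )
    return data, edges
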
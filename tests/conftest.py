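import numpy as np
import pytest

from dicore.collaboration import CollaborationMatrix
from dicore.io import ExpressionMatrix, MatchedPair
from dicore.synthetic import PlantedScenario, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair():
    """4 miRNAs x 6 mRNAs x 8 samples with two exactly-dependent features."""
    rng = np.random.default_rng(7)
    n = 8
    X = rng.normal(size=(4, n))
    Y = rng.normal(size=(6, n))
    Y[0] = 2.0 * X[0] + 3.0          # perfect positive dependence
    Y[1] = -X[1]                     # perfect negative dependence
    samples = [f"s{i}" for i in range(n)]
    return MatchedPair(
        mirna=ExpressionMatrix([f"m{i}" for i in range(4)], samples, X),
        mrna=ExpressionMatrix([f"g{j}" for j in range(6)], samples, Y),
    )


@pytest.fixture(scope="session")
def default_scenario_run():
    """Default planted scenario (seed 1) with its ground truth."""
    return generate(PlantedScenario(seed=1))


def two_block_matrix():
    """Disjoint blocks of size 4 and 5: within-score 1, between-score 0."""
    ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(5)]
    S = np.zeros((9, 9))
    S[:4, :4] = 1.0
    S[4:, 4:] = 1.0
    np.fill_diagonal(S, 0.0)
    return CollaborationMatrix(ids=ids, scores=S)


@pytest.fixture
def two_blocks():
    return two_block_matrix()
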
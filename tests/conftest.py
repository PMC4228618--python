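import numpy as np
import pytest

from haplopop import AlleleMatrix, StrataMap, paper_shaped_dataset


@pytest.fixture
def tiny_matrix():
    """4 individuals x 3 loci, one missing call."""
    calls = np.array([
        [5, 7, 9],
        [5, 8, 9],
        [6, 7, 0],
        [5, 7, 9],
    ])
    return AlleleMatrix(("a", "b", "c", "d"), ("L1", "L2", "L3"), calls)


@pytest.fixture
def tiny_strata():
    return StrataMap.from_labels(["a", "b", "c", "d"],
                                 tree=["1", "1", "2", "2"],
                                 age_class=["new", "old", "new", "old"])


@pytest.fixture(scope="session")
def survey():
    """One survey-shaped synthetic dataset (92 x 12, 21 strata), fixed seed."""
    return paper_shaped_dataset(seed=123)


def random_matrix(rng, n, L, n_alleles=3, missing_rate=0.0):
    calls = rng.integers(1, n_alleles + 1, size=(n, L))
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = 0
    return AlleleMatrix(tuple(f"i{k}" for k in range(n)),
                        tuple(f"L{j}" for j in range(L)), calls)
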
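import numpy as np
import pytest

from mdbs import (
    Alternative,
    DecisionProblem,
    DimensionSpec,
    HIGHER_BETTER,
    LOWER_BETTER,
    ModelParams,
    load_fixture,
)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def cars():
    return load_fixture("synthetic_big_three")


@pytest.fixture
def car_pair(cars):
    return cars.subset(["A", "B"])


def random_problem(rng, n_alts=None, n_dims=None, with_context=False):
    """Random nondegenerate multiattribute problem for property tests."""
    n_alts = n_alts or int(rng.integers(2, 4))
    n_dims = n_dims or int(rng.integers(2, 4))
    dims = [
        DimensionSpec(
            f"d{j}",
            HIGHER_BETTER if rng.random() < 0.5 else LOWER_BETTER,
        )
        for j in range(n_dims)
    ]
    alts = [
        Alternative(
            f"a{i}",
            {d.name: float(rng.uniform(0.5, 50.0)) for d in dims},
        )
        for i in range(n_alts)
    ]
    ctx = {}
    if with_context:
        k = dims[0].name
        ctx[k] = [float(rng.uniform(0.5, 50.0)) for _ in range(2)]
    return DecisionProblem(dims, alts, ctx)
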
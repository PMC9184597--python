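import numpy as np
import pytest

from gelrsm import rsm


@pytest.fixture(scope="session")
def space():
    return rsm.reference_space()


@pytest.fixture(scope="session")
def printed_actual():
    return rsm.printed_actual_model()


@pytest.fixture(scope="session")
def printed_coded():
    return rsm.printed_coded_model()


@pytest.fixture(scope="session")
def refined():
    return rsm.reference_model()


def random_quadratic_model(rng: np.random.Generator, space=None) -> rsm.QuadraticModel:
    """Random full-quadratic model over a random (or given) 4-factor box."""
    if space is None:
        factors = []
        for name in ("gelma", "time", "hase", "hama"):
            low = rng.uniform(-10, 10)
            high = low + rng.uniform(0.5, 20)
            factors.append(rsm.Factor(name, "u", low, high))
        space = rsm.DesignSpace(tuple(factors))
    names = space.names
    linear = {n: rng.normal(scale=5) for n in names}
    interaction = {
        (a, b): rng.normal(scale=2)
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    quadratic = {n: rng.normal(scale=1) for n in names}
    return rsm.QuadraticModel(
        form=rsm.FORM_ACTUAL,
        intercept=rng.normal(scale=20),
        linear=linear,
        interaction=interaction,
        quadratic=quadratic,
        space=space,
    )
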
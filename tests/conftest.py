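import numpy as np
import pytest

from stagesel import SynthSpec, generate_table


def random_decision_values(rng, m=None, n=None):
    """Strictly positive random matrix for MCDM property tests."""
    m = m or rng.integers(2, 11)
    n = n or rng.integers(2, 6)
    return rng.uniform(0.1, 10.0, size=(m, n))


@pytest.fixture
def separable_table():
    """Two well-separated Gaussian blobs: any sane classifier is perfect."""
    return generate_table(
        SynthSpec(
            n_samples=80,
            class_counts=(50, 30),
            n_informative=3,
            n_redundant=0,
            n_noise=2,
            effect_size=8.0,
            seed=11,
        )
    )


@pytest.fixture
def small_signal_table():
    """Moderate-signal table for selection/ensemble tests."""
    return generate_table(
        SynthSpec(
            n_samples=80,
            class_counts=(50, 30),
            n_informative=5,
            n_redundant=0,
            n_noise=20,
            effect_size=1.5,
            seed=5,
        )
    )


def make_matrix(values, directions=None):
    from stagesel import DecisionMatrix

    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return DecisionMatrix(
        values=values,
        directions=tuple(directions) if directions else ("benefit",) * n,
        alternative_ids=tuple(f"a{i}" for i in range(m)),
        criterion_ids=tuple(f"c{j}" for j in range(n)),
    )
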
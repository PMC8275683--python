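import numpy as np
import pytest

from implinet.core_io import ExpressionMatrix, SampleAnnotation
from implinet.synthetic_data import ModuleSpec, SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([
            [1.0, 1.0, 5.0, 5.0],
            [5.0, 5.0, 1.0, 1.0],
            [2.0, 2.0, 2.0, 2.0],
        ]),
    )


@pytest.fixture
def small_annotation():
    return SampleAnnotation.from_labels(
        ["s1", "s2", "s3", "s4"], ["healthy", "healthy", "disease", "disease"]
    )


def planted_spec(seed=0, n_samples=200, delta=4.0, sizes=((20, "healthy_up"), (15, "healthy_up"), (10, "disease_up")), n_noise=20):
    return SyntheticSpec(
        n_samples=n_samples,
        modules=[ModuleSpec(size, side, delta) for size, side in sizes],
        n_noise_genes=n_noise,
        seed=seed,
    )


@pytest.fixture
def planted_cohort():
    return generate_cohort(planted_spec(seed=7))
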
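import numpy as np
import pytest

import cohortshift as cs
from cohortshift.cohorts import GroupLabelModel


@pytest.fixture
def small_cohort():
    """Two balanced groups, 10 numeric + 2 categorical features, no missingness."""
    spec = cs.CohortSpec(
        n_per_group={"A": 120, "B": 80},
        n_numeric=10,
        shift_vector={"B": np.r_[np.ones(3), np.zeros(7)]},
        class_balance=0.5,
        seed=7,
    )
    return cs.generate_cohort(spec)


@pytest.fixture
def benchmark_cohort():
    """The moderate-shift two-group benchmark condition at reduced size."""
    return cs.generate_cohort(cs.adaptation_benchmark_spec(m=400, n=120, seed=11))


def shifted_gaussians(n, d, shift, seed):
    """Paired samples: standard normal vs mean-shifted normal."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, d)), rng.standard_normal((n, d)) + shift


def make_label_model(coef, **kw):
    return GroupLabelModel(coef=np.asarray(coef, float), **kw)
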
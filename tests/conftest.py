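import numpy as np
import pytest

from braingap.synthetic import (
    CohortSpec,
    VariableSpec,
    apply_missingness,
    default_cohort_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def null_cohort():
    """Default 335-subject cohort (3 gaps, 27 mixed-type criteria, Table-style
    missingness) with no planted effects."""
    spec = default_cohort_spec(seed=7)
    return apply_missingness(generate_cohort(spec), seed=8)


@pytest.fixture(scope="session")
def small_cohort():
    """Small complete cohort with five normal criteria, no planted effects."""
    spec = CohortSpec(
        n_subjects=120,
        variables=tuple(VariableSpec(name=f"c{i}", expected_sign=(-1) ** i)
                        for i in range(5)),
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
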
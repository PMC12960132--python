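import numpy as np
import pytest

from facenorms.anthropometry import DEFAULT_REGISTRY
from facenorms.synthetic import make_cohort_spec, simulate_cohort, simulate_landmarks


@pytest.fixture(scope="session")
def chinese_spec():
    return make_cohort_spec("chinese")


@pytest.fixture(scope="session")
def european_spec():
    return make_cohort_spec("european")


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 200-subject chinese-preset cohort table."""
    return simulate_cohort(make_cohort_spec("chinese", n=200, seed=7))


@pytest.fixture()
def symmetric_face(chinese_spec):
    """A noiseless landmark set realising age-10 male mean measurements."""
    values = {d.name: float(chinese_spec.mean(d.name, "M", 10.0)) for d in DEFAULT_REGISTRY}
    return simulate_landmarks(values, subject_id="demo"), values


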
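import dataclasses

import numpy as np
import pytest

import eecgnet as e


@pytest.fixture
def clean_template():
    return e.make_subject_template(7)


@pytest.fixture
def zero_jitter_template(clean_template):
    return dataclasses.replace(clean_template, rr_jitter_sd=0.0)


@pytest.fixture
def clean_record(zero_jitter_template):
    """10 clean beats at 360 Hz."""
    t = zero_jitter_template
    return e.synthesize_record(t, duration=10 * t.base_rr, fs=360.0,
                               noise=e.NoiseSpec.clean(), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 4 records, default (moderate) noise, single CU-like lead."""
    return e.generate_cohort(6, 4, duration=8.0, fs=500.0,
                             noise=e.NoiseSpec(), seed=5)


@pytest.fixture(scope="session")
def random_images():
    rng = np.random.default_rng(42)
    return [rng.normal(size=(8, 8)) for _ in range(20)]
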
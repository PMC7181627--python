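import numpy as np
import pytest
from hypothesis import settings

import hydroseg as hs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> hs.PhantomSpec:
    """Noiseless desk-scale phantom spec (24-px crop windows)."""
    return hs.PhantomSpec(noise_sd=0.0, endolymph_fraction=0.35, seed=7).scaled(0.24)


@pytest.fixture(scope="session")
def small_subject(small_spec) -> hs.SubjectStack:
    return hs.generate_subject(small_spec, "subject-small")


@pytest.fixture(scope="session")
def full_spec() -> hs.PhantomSpec:
    """Full-geometry (384x324, 100-px windows) noiseless spec."""
    return hs.PhantomSpec(noise_sd=0.0, endolymph_fraction=0.35, seed=7)


@pytest.fixture(scope="session")
def full_subject(full_spec) -> hs.SubjectStack:
    return hs.generate_subject(full_spec, "subject-full")


@pytest.fixture(scope="session")
def tiny_cohort(small_spec):
    subjects, manifest = hs.generate_cohort(
        6,
        small_spec,
        hs.CohortRanges(endolymph_fraction=(0.1, 0.6), noise_sd=(40.0, 40.0)),
        seed=11,
    )
    return subjects, manifest
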
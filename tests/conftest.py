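import numpy as np
import pytest

from cortinterp import (
    CohortConfig,
    Profile,
    build_scheme,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 8-subject cohort (seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture()
def quiet_config():
    """A config with every random component switched off."""
    return CohortConfig(
        noise_sd_serum=0.0,
        noise_sd_saliva=0.0,
        ultradian_amplitude=0.0,
        between_subject_sd=0.0,
        seed=0,
    )


@pytest.fixture()
def serum_rest_profile(default_cohort):
    return next(
        p
        for p in default_cohort
        if p.specimen == "serum" and p.condition == "rest" and p.subject_id == "S1"
    )


def make_profile(values, times=None, **kwargs):
    """Helper: a serum rest profile on the Q60 grid (or given times)."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = build_scheme("Q60").grid_minutes[: len(values)]
    defaults = dict(subject_id="T1", condition="rest", specimen="serum")
    defaults.update(kwargs)
    return Profile(times=np.asarray(times, dtype=float), values=values, **defaults)
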
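import numpy as np
import pytest

from tlfbimpute.simulate import GeneratorConfig, simulate_cohort
from tlfbimpute.timeline import DAY_MIN, N_DAYS, SubjectTimeline


def make_timeline(
    subject_id="A",
    site="SA",
    start_weekday=0,
    observed_days=None,
    values=None,
    fill=0.0,
):
    """Build a timeline observed on ``observed_days`` (gestational day
    indices; None = fully observed) holding ``values`` (scalar or mapping
    day->drinks, default ``fill``)."""
    drinks = np.full(N_DAYS, np.nan)
    observed = np.zeros(N_DAYS, dtype=bool)
    if observed_days is None:
        observed_days = range(DAY_MIN, DAY_MIN + N_DAYS)
    for d in observed_days:
        pos = d - DAY_MIN
        observed[pos] = True
        if isinstance(values, dict):
            drinks[pos] = values.get(d, fill)
        elif values is not None:
            drinks[pos] = values
        else:
            drinks[pos] = fill
    return SubjectTimeline(
        subject_id=subject_id,
        site=site,
        start_weekday=start_weekday,
        drinks=drinks,
        observed=observed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject mixed-site synthetic cohort (observed timelines)."""
    _, sa = simulate_cohort(GeneratorConfig(n_subjects=30, site_profile="SA", rng_seed=42))
    _, np_ = simulate_cohort(GeneratorConfig(n_subjects=30, site_profile="NP", rng_seed=43))
    return sa + np_


@pytest.fixture(scope="session")
def cohort500():
    """The standard two-site validation cohort: 250 late-enrolling (SA-like)
    and 250 early-enrolling (NP-like) subjects."""
    _, sa = simulate_cohort(GeneratorConfig(n_subjects=250, site_profile="SA", rng_seed=0))
    _, np_ = simulate_cohort(GeneratorConfig(n_subjects=250, site_profile="NP", rng_seed=1))
    return sa + np_


@pytest.fixture(scope="session")
def small_cohort_with_truth():
    """(complete, observed) pair for a 40-subject cohort."""
    comp, obs = simulate_cohort(GeneratorConfig(n_subjects=40, site_profile="NP", rng_seed=7))
    return comp, obs
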
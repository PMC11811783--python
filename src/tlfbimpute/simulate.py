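"""Synthetic pregnancy-drinking cohorts with TLFB-style missingness.

The generator produces pairs of (complete, observed) timelines so that
ground truth is always available.  Complete timelines follow the structure
the imputer assumes: subjects belong to behavioral classes (abstainer,
quitter, reducer, persistent), drinking is weekend-heavy via weekday
multipliers, and quitters/reducers change behavior at a random
pregnancy-recognition day.  The observation mask reproduces the reporting
instrument: the +/-15-day window around the LMP is always recorded, and at
each study visit the subject reports her last drinking day plus the 30 days
before it — so the span from 30 days before the last drinking day up to the
visit is known, and anything earlier (since the previous covered span) is
missing.  Subjects with no drinking before a visit have nothing to leave a
gap: their record is complete up to that visit.  This makes missingness
informative by design — the more recently a subject drank, the more days
she is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeline import DAY_MAX, DAY_MIN, N_DAYS, SubjectTimeline, day_to_pos

CLASSES = ("abstainer", "quitter", "reducer", "persistent")

#: Default per-class share of the cohort.  Roughly 62% of subjects drink at
#: some point; most of those reduce or stop after recognizing the pregnancy.
DEFAULT_CLASS_PROBS = {
    "abstainer": 0.38,
    "quitter": 0.30,
    "reducer": 0.17,
    "persistent": 0.15,
}

#: Mon..Sun multipliers on the daily drinking probability; weekends heavy.
DEFAULT_WEEKDAY_MULTIPLIERS = (0.5, 0.5, 0.6, 0.8, 1.6, 2.2, 0.9)

#: Default study-visit schedules (gestational days).  The SA-like profile
#: enrolls late — its first visit falls well into trimester 2 — which
#: concentrates missing days in early pregnancy; the NP-like profile
#: enrolls early.  The final visit (postpartum) covers the end of pregnancy.
SITE_VISIT_DAYS = {
    "SA": (100, 170, 240, 310),
    "NP": (50, 120, 190, 260, 310),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``drink_prob`` is the per-class baseline probability of drinking on a
    given day before the weekday multiplier; ``base_rate`` the mean
    standard drinks on a drinking day (amounts are right-skewed lognormal,
    continuous).  ``recognition_day`` bounds the uniform distribution of
    the pregnancy-recognition day at which quitters stop and reducers damp
    consumption by ``reduction_factor``.

    Drinking is habitual, not a nightly coin flip: each drinker carries a
    subject-specific weekday-propensity profile (the population weekday
    multipliers perturbed by a lognormal factor of scale ``habit_sigma``,
    renormalized) and a subject-level consumption multiplier of scale
    ``level_sigma``, so one subject reliably drinks on, say, Fridays and
    Saturdays while another favors different days.  This within-subject
    regularity is what makes drinking timelines pattern-matchable at all.
    """

    n_subjects: int = 200
    site_profile: str = "SA"  # "SA" (late enrollment) or "NP" (early)
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    weekday_multipliers: tuple = DEFAULT_WEEKDAY_MULTIPLIERS
    drink_prob: dict = field(
        default_factory=lambda: {"abstainer": 0.0, "quitter": 0.35, "reducer": 0.35, "persistent": 0.40}
    )
    base_rate: dict = field(
        default_factory=lambda: {"abstainer": 0.0, "quitter": 3.0, "reducer": 4.0, "persistent": 5.0}
    )
    lognormal_sigma: float = 0.5
    habit_sigma: float = 0.9
    level_sigma: float = 0.4
    recognition_day: tuple[int, int] = (30, 90)
    reduction_factor: float = 0.3
    visit_days: tuple | None = None  # None -> site profile default
    visit_jitter: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_probs must sum to 1, got {total}")
        if any(m < 0 for m in self.weekday_multipliers) or len(self.weekday_multipliers) != 7:
            raise ValueError("weekday_multipliers must be 7 nonnegative reals")
        if self.site_profile not in SITE_VISIT_DAYS and self.visit_days is None:
            raise ValueError(f"unknown site profile {self.site_profile!r} and no visit_days")


def _simulate_subject(
    cfg: GeneratorConfig, rng: np.random.Generator, subject_id: str
) -> tuple[SubjectTimeline, SubjectTimeline]:
    cls = rng.choice(CLASSES, p=[cfg.class_probs.get(c, 0.0) for c in CLASSES])
    start_weekday = int(rng.integers(7))
    recognition = int(rng.integers(cfg.recognition_day[0], cfg.recognition_day[1] + 1))

    days = np.arange(DAY_MIN, DAY_MAX + 1)
    weekdays = (start_weekday + (days - DAY_MIN)) % 7
    # subject-specific habitual weekday profile and consumption level
    base_mult = np.asarray(cfg.weekday_multipliers, dtype=float)
    habit = base_mult * rng.lognormal(mean=0.0, sigma=cfg.habit_sigma, size=7)
    habit *= base_mult.mean() / habit.mean() if habit.mean() > 0 else 1.0
    level = rng.lognormal(mean=0.0, sigma=cfg.level_sigma)
    p = cfg.drink_prob[cls] * habit[weekdays]
    # class-specific behavior change at pregnancy recognition
    after = days > recognition
    if cls == "quitter":
        p = np.where(after, 0.0, p)
    elif cls == "reducer":
        p = np.where(after, p * cfg.reduction_factor, p)
    p = np.clip(p, 0.0, 1.0)

    drinking_day = rng.random(N_DAYS) < p
    mu = np.log(max(cfg.base_rate[cls], 1e-12)) - cfg.lognormal_sigma**2 / 2
    amounts = level * rng.lognormal(mean=mu, sigma=cfg.lognormal_sigma, size=N_DAYS)
    if cls == "reducer":
        amounts = np.where(after, amounts * cfg.reduction_factor, amounts)
    complete_drinks = np.where(drinking_day, amounts, 0.0)

    # --- observation mask: LMP window + per-visit reporting windows -------
    observed = np.zeros(N_DAYS, dtype=bool)
    observed[day_to_pos(DAY_MIN) : day_to_pos(15) + 1] = True  # +/-15 days around LMP
    visits = cfg.visit_days if cfg.visit_days is not None else SITE_VISIT_DAYS[cfg.site_profile]
    jittered = []
    for i, v in enumerate(visits):
        if i < len(visits) - 1 and cfg.visit_jitter > 0:
            v = int(v + rng.integers(-cfg.visit_jitter, cfg.visit_jitter + 1))
        jittered.append(int(np.clip(v, 20, DAY_MAX)))
    for v in sorted(jittered):
        vpos = day_to_pos(v)
        drink_pos = np.flatnonzero(complete_drinks[: vpos + 1] > 0)
        if len(drink_pos) == 0:
            observed[: vpos + 1] = True  # nothing to recall: record complete
        else:
            last = drink_pos[-1]
            observed[max(last - 29, 0) : vpos + 1] = True

    complete = SubjectTimeline(
        subject_id=subject_id,
        site=cfg.site_profile,
        start_weekday=start_weekday,
        drinks=complete_drinks,
        observed=np.ones(N_DAYS, dtype=bool),
    )
    obs = SubjectTimeline(
        subject_id=subject_id,
        site=cfg.site_profile,
        start_weekday=start_weekday,
        drinks=np.where(observed, complete_drinks, np.nan),
        observed=observed,
    )
    return complete, obs


def simulate_cohort(
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[list[SubjectTimeline], list[SubjectTimeline]]:
    """Generate a cohort; returns (complete, observed) timeline lists.

    The observed timelines are restrictions of the complete ones, so every
    downstream result can be checked against ground truth.  ``seed``
    overrides ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    width = len(str(max(config.n_subjects - 1, 1)))
    complete, observed = [], []
    for i in range(config.n_subjects):
        c, o = _simulate_subject(config, rng, f"{config.site_profile}-{i:0{width}d}")
        complete.append(c)
        observed.append(o)
    return complete, observed


def missingness_summary(timelines: list[SubjectTimeline]) -> dict[str, float]:
    """Cohort-level missingness and drinking prevalence percentages."""
    if not timelines:
        raise ValueError("missingness_summary needs a nonempty cohort")
    total_days = len(timelines) * N_DAYS
    missing = sum(t.n_missing() for t in timelines)
    complete = sum(1 for t in timelines if t.n_missing() == 0)
    drinkers = sum(1 for t in timelines if np.nansum(t.drinks) > 0)
    return {
        "pct_person_days_missing": 100.0 * missing / total_days,
        "pct_subjects_complete": 100.0 * complete / len(timelines),
        "pct_drinkers": 100.0 * drinkers / len(timelines),
    }
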
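"""Winsorization, cohort exclusion filters and weekday alignment.

Timelines from different subjects are only comparable day-by-day when the
compared days fall on the same weekday, because drinking is strongly
weekday-patterned (weekend-heavy).  Each subject carries the weekday of her
gestational day -15, derived from the calendar distance between the
pregnancy start and a fixed anchor (Saturday, 1 January 2000); aligning two
subjects means shifting one timeline by 0..6 days so the weekday grids
coincide.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeline import (
    DAY_MAX,
    DAY_MIN,
    N_DAYS,
    SATURDAY,
    SiteConfig,
    SubjectTimeline,
    day_to_pos,
)

#: Calendar anchor used to derive weekdays: Saturday, 1 January 2000.
ANCHOR_DATE = _dt.date(2000, 1, 1)
ANCHOR_WEEKDAY = SATURDAY
assert ANCHOR_DATE.weekday() == ANCHOR_WEEKDAY

#: Trimester day ranges (inclusive), 13 weeks each from LMP; day 0 itself
#: belongs to the periconceptional window [-15, 0].
TRIMESTER_1 = (1, 93)
TRIMESTER_2 = (94, 186)
TRIMESTER_3 = (187, 310)
PERICONCEPTIONAL = (DAY_MIN, 0)

#: Exclusion thresholds: subjects with no observed trimester-1 day or with
#: more than this many missing days are unusable for pattern matching.
MAX_MISSING_DAYS = 200


def weekday_of_day(start_weekday: int, day: int) -> int:
    """Weekday (0 = Monday .. 6 = Sunday) of a gestational day.

    ``start_weekday`` is the weekday of day -15.
    """
    if not (0 <= start_weekday <= 6):
        raise ValueError(f"start_weekday must be 0..6, got {start_weekday}")
    if not (DAY_MIN <= day <= DAY_MAX):
        raise ValueError(f"day {day} outside [{DAY_MIN}, {DAY_MAX}]")
    return (start_weekday + (day - DAY_MIN)) % 7


def start_weekday_from_date(day_minus15: _dt.date) -> int:
    """Weekday of day -15 from its calendar date, via the Saturday
    2000-01-01 anchor."""
    delta = (day_minus15 - ANCHOR_DATE).days
    return (ANCHOR_WEEKDAY + delta) % 7


@dataclass(frozen=True)
class AlignmentMap:
    """Weekday alignment of a candidate timeline q onto a query timeline p.

    ``shift`` is the number of leading days of q dropped so that position
    i of p pairs with position i + shift of q on the same weekday: p's day
    d corresponds to q's day d + shift.  The last ``shift`` days of p have
    no partner and are likewise dropped.
    """

    shift: int

    def q_day_for(self, p_day: int) -> int:
        """The q day index aligned with a given p day (may exceed DAY_MAX
        for the dropped tail of p)."""
        return p_day + self.shift

    @property
    def dropped_head_q(self) -> int:
        return self.shift

    @property
    def dropped_tail_p(self) -> int:
        return self.shift


def align(p: SubjectTimeline, q: SubjectTimeline) -> AlignmentMap:
    """Compute the weekday-matching shift of q relative to p.

    The shift is the smallest nonnegative number of days such that q's day
    (-15 + shift) falls on the same weekday as p's day -15.
    """
    shift = (p.start_weekday - q.start_weekday) % 7
    return AlignmentMap(shift=shift)


# ---------------------------------------------------------------------------
# Winsorization
# ---------------------------------------------------------------------------

def resolve_caps(
    timelines: list[SubjectTimeline],
    site_configs: dict[str, SiteConfig] | None = None,
) -> dict[str, float]:
    """Resolve a Winsorization cap per site.

    Explicit caps pass through; "auto" (and sites without a config) get
    mean + 3 SD of drinks over the site's observed drinking days
    (drinks > 0).  Auto with no drinking days at a site is an error.
    """
    site_configs = site_configs or {}
    caps: dict[str, float] = {}
    sites = sorted({t.site for t in timelines})
    for site in sites:
        cfg = site_configs.get(site, SiteConfig(name=site, winsor_cap="auto"))
        if cfg.winsor_cap != "auto":
            caps[site] = float(cfg.winsor_cap)
            continue
        vals = np.concatenate(
            [t.drinks[t.observed & (t.drinks > 0)] for t in timelines if t.site == site]
        ) if any(t.site == site for t in timelines) else np.array([])
        if vals.size == 0:
            raise ValueError(f"site {site}: cannot compute auto cap without drinking days")
        caps[site] = float(vals.mean() + 3 * vals.std(ddof=1 if vals.size > 1 else 0))
    return caps


def winsorize(timeline: SubjectTimeline, cap: float) -> SubjectTimeline:
    """Cap observed drinks at ``cap``; the observation mask is untouched."""
    if not cap > 0:
        raise ValueError(f"cap must be > 0, got {cap}")
    out = timeline.copy()
    out.drinks = np.where(out.observed, np.minimum(out.drinks, cap), np.nan)
    return out


def winsorize_cohort(
    timelines: list[SubjectTimeline],
    site_configs: dict[str, SiteConfig] | None = None,
) -> tuple[list[SubjectTimeline], dict[str, float]]:
    """Winsorize every timeline at its site's (resolved) cap."""
    caps = resolve_caps(timelines, site_configs)
    return [winsorize(t, caps[t.site]) for t in timelines], caps


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

REASON_NO_T1 = "no_trimester1_data"
REASON_TOO_MANY_MISSING = "more_than_200_missing_days"


def apply_exclusions(
    timelines: list[SubjectTimeline],
    trimester1: tuple[int, int] = TRIMESTER_1,
    max_missing: int = MAX_MISSING_DAYS,
) -> tuple[list[SubjectTimeline], pd.DataFrame]:
    """Drop subjects whose drinking pattern cannot be established.

    A subject is kept iff she has at least one observed day inside
    trimester 1 and at most ``max_missing`` unobserved days overall.
    Returns (kept, dropped) where dropped is a DataFrame of
    (subject_id, reason) naming the first triggering rule.
    """
    lo, hi = day_to_pos(trimester1[0]), day_to_pos(trimester1[1])
    kept: list[SubjectTimeline] = []
    dropped: list[dict] = []
    for t in timelines:
        if not t.observed[lo : hi + 1].any():
            dropped.append({"subject_id": t.subject_id, "reason": REASON_NO_T1})
        elif t.n_missing() > max_missing:
            dropped.append({"subject_id": t.subject_id, "reason": REASON_TOO_MANY_MISSING})
        else:
            kept.append(t)
    return kept, pd.DataFrame(dropped, columns=["subject_id", "reason"])
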
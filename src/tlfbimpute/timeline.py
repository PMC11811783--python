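"""Core domain types and long-format I/O for daily drinking timelines.

A pregnancy timeline is indexed by gestational day relative to the last
menstrual period (LMP, day 0), running from day -15 (two weeks before LMP,
the start of the periconceptional reporting window) through day 310 (the
maximum pregnancy length) — 326 positions in total.  Each position either
holds an observed number of standard drinks (a nonnegative real) or is
missing.  The canonical on-disk representation is a long CSV with one row
per observed (subject, day) pair; the wide day-indexed vector lives only in
memory.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: First and last gestational day of a timeline (inclusive).
DAY_MIN = -15
DAY_MAX = 310
#: Number of day positions in a timeline vector.
N_DAYS = DAY_MAX - DAY_MIN + 1  # 326

#: Weekday convention: 0 = Monday .. 6 = Sunday (ISO order).
MONDAY, TUESDAY, WEDNESDAY, THURSDAY, FRIDAY, SATURDAY, SUNDAY = range(7)
WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Known study-site labels; anything else is carried through as "other".
SITES = ("SA", "NP", "other")

PROV_OBSERVED = "observed"
PROV_IMPUTED = "imputed"
PROV_CHAINED = "imputed_chained"


def day_to_pos(day: int | np.ndarray) -> int | np.ndarray:
    """Map a gestational day index (-15..310) to a 0-based vector position."""
    return day - DAY_MIN


def pos_to_day(pos: int | np.ndarray) -> int | np.ndarray:
    """Map a 0-based vector position to a gestational day index."""
    return pos + DAY_MIN


@dataclass
class SubjectTimeline:
    """One subject's day-indexed drinks vector with missingness mask.

    Parameters
    ----------
    subject_id:
        Opaque subject identifier.
    site:
        Study-site label ("SA", "NP" or "other").
    start_weekday:
        Weekday of gestational day -15, with 0 = Monday .. 6 = Sunday.
    drinks:
        Length-326 float vector of standard drinks per day; NaN where
        unobserved.
    observed:
        Length-326 boolean mask; ``drinks[i]`` is finite iff
        ``observed[i]``.
    provenance:
        Optional length-326 object array of per-day provenance flags
        ("observed", "imputed", "imputed_chained"); None for a timeline
        that has not been through imputation.
    """

    subject_id: str
    site: str
    start_weekday: int
    drinks: np.ndarray
    observed: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.drinks = np.asarray(self.drinks, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.drinks.shape != (N_DAYS,) or self.observed.shape != (N_DAYS,):
            raise ValueError(
                f"timeline vectors must have length {N_DAYS}, got "
                f"{self.drinks.shape} / {self.observed.shape}"
            )
        if not (0 <= int(self.start_weekday) <= 6):
            raise ValueError(f"start_weekday must be 0..6, got {self.start_weekday}")
        obs_vals = self.drinks[self.observed]
        if np.any(~np.isfinite(obs_vals)):
            raise ValueError(f"subject {self.subject_id}: observed day with non-finite drinks")
        if np.any(obs_vals < 0):
            raise ValueError(f"subject {self.subject_id}: negative drinks value")
        # unobserved positions are forced to NaN so stale values cannot leak
        self.drinks = np.where(self.observed, self.drinks, np.nan)

    # -- convenience accessors -------------------------------------------------

    def value_on(self, day: int) -> float:
        return float(self.drinks[day_to_pos(day)])

    def n_missing(self) -> int:
        return int((~self.observed).sum())

    def copy(self) -> "SubjectTimeline":
        return replace(
            self,
            drinks=self.drinks.copy(),
            observed=self.observed.copy(),
            provenance=None if self.provenance is None else self.provenance.copy(),
        )


@dataclass(frozen=True)
class SiteConfig:
    """Per-site Winsorization settings.

    ``winsor_cap`` is either a positive number of standard drinks or the
    string "auto", in which case the cap is computed from the cohort as
    mean + 3 SD of drinks over observed drinking days (drinks > 0) at that
    site.
    """

    name: str
    winsor_cap: float | str = "auto"

    def __post_init__(self) -> None:
        if self.winsor_cap != "auto" and not float(self.winsor_cap) > 0:
            raise ValueError(f"explicit winsor cap must be > 0, got {self.winsor_cap}")


@dataclass(frozen=True)
class ImputationConfig:
    """Tunable parameters of the k-NN imputation algorithm.

    Attributes
    ----------
    k:
        Number of nearest neighbors averaged per missing day.
    segment_length:
        Length L (days) of reference segments and query windows.
    min_overlap:
        Minimum number of observed context days a query window must hold.
    position_tolerance:
        Maximum |segment start - window start| in days for a candidate
        segment, or None for unconstrained gestational position.
    include_self_segments:
        Whether a subject's own gap-free segments may serve as neighbors
        (segments overlapping the gap being filled are always excluded).
    classify_threshold:
        Total drinks at or above which an imputed segment is classified as
        drinking.
    stride:
        Step between candidate segment start positions (1 = maximally
        overlapping).
    """

    k: int = 5
    segment_length: int = 55
    min_overlap: int = 7
    position_tolerance: int | None = 28
    include_self_segments: bool = True
    classify_threshold: float = 0.5
    stride: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if not (1 <= self.min_overlap <= self.segment_length):
            raise ValueError("min_overlap must be in 1..segment_length")
        if self.position_tolerance is not None and self.position_tolerance < 0:
            raise ValueError("position_tolerance must be >= 0 or None")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["subject_id", "site", "day", "drinks"]


def read_long(
    source: str | Path | io.TextIOBase | pd.DataFrame,
    start_weekdays: Mapping[str, int] | None = None,
) -> list[SubjectTimeline]:
    """Read long-format records into wide timelines.

    ``source`` is a CSV path/handle or a DataFrame with columns
    subject_id, site, day, drinks and optionally start_weekday (weekday of
    day -15, 0 = Monday).  Per-subject start weekdays may instead be
    supplied through ``start_weekdays``; subjects absent from both default
    to Monday.

    Days absent from the input become unobserved positions.  Duplicate
    (subject, day) rows, out-of-range days and negative drinks are hard
    errors.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        # round_trip parsing so write_long -> read_long is bit-exact
        df = pd.read_csv(source, float_precision="round_trip")
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long-format input lacks columns: {missing_cols}")

    df["day"] = df["day"].astype(int)
    bad_day = df[(df["day"] < DAY_MIN) | (df["day"] > DAY_MAX)]
    if len(bad_day):
        r = bad_day.iloc[0]
        raise ValueError(
            f"day {r['day']} for subject {r['subject_id']} outside [{DAY_MIN}, {DAY_MAX}]"
        )
    dup = df.duplicated(subset=["subject_id", "day"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(f"duplicate record for subject {r['subject_id']} day {r['day']}")
    neg = df[df["drinks"] < 0]
    if len(neg):
        r = neg.iloc[0]
        raise ValueError(f"negative drinks for subject {r['subject_id']} day {r['day']}")

    timelines: list[SubjectTimeline] = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        drinks = np.full(N_DAYS, np.nan)
        observed = np.zeros(N_DAYS, dtype=bool)
        pos = day_to_pos(grp["day"].to_numpy())
        drinks[pos] = grp["drinks"].to_numpy(dtype=float)
        observed[pos] = True
        provenance = None
        if "provenance" in grp.columns:
            provenance = np.array([None] * N_DAYS, dtype=object)
            provenance[pos] = grp["provenance"].to_numpy()
        if "start_weekday" in grp.columns:
            wd = int(grp["start_weekday"].iloc[0])
        elif start_weekdays is not None and subject_id in start_weekdays:
            wd = int(start_weekdays[subject_id])
        else:
            wd = MONDAY
        site = str(grp["site"].iloc[0])
        timelines.append(
            SubjectTimeline(
                subject_id=str(subject_id),
                site=site,
                start_weekday=wd,
                drinks=drinks,
                observed=observed,
                provenance=provenance,
            )
        )
    return timelines


def write_long(
    timelines: Iterable[SubjectTimeline],
    path: str | Path | io.TextIOBase | None = None,
    include_provenance: bool = False,
) -> pd.DataFrame:
    """Serialize timelines to long-format rows (one row per defined day).

    Returns the DataFrame; also writes CSV when ``path`` is given.  With
    ``include_provenance`` each row carries a flag telling whether the
    value was observed or produced by imputation.
    """
    frames = []
    for t in timelines:
        pos = np.flatnonzero(t.observed)
        frame = {
            "subject_id": t.subject_id,
            "site": t.site,
            "day": pos_to_day(pos),
            "drinks": t.drinks[pos],
            "start_weekday": t.start_weekday,
        }
        if include_provenance:
            if t.provenance is None:
                frame["provenance"] = PROV_OBSERVED
            else:
                frame["provenance"] = t.provenance[pos]
        frames.append(pd.DataFrame(frame))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        cols = LONG_COLUMNS + ["start_weekday"]
        if include_provenance:
            cols.append("provenance")
        df = pd.DataFrame(columns=cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Flat key:value configuration files
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[ImputationConfig, dict[str, SiteConfig]]:
    """Load imputation and per-site settings from a flat YAML mapping.

    Recognized keys mirror :class:`ImputationConfig` fields; keys of the
    form ``winsor_cap_<site>`` define per-site caps (number or "auto").
    Unknown keys are rejected so typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key: value mapping")
    imp_kwargs: dict = {}
    sites: dict[str, SiteConfig] = {}
    imp_fields = set(ImputationConfig.__dataclass_fields__)
    for key, value in raw.items():
        if key in imp_fields:
            if key == "position_tolerance" and value in ("unbounded", None):
                value = None
            imp_kwargs[key] = value
        elif key.startswith("winsor_cap_"):
            site = key[len("winsor_cap_"):]
            sites[site] = SiteConfig(name=site, winsor_cap=value)
        else:
            raise ValueError(f"unknown config key: {key}")
    return ImputationConfig(**imp_kwargs), sites
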
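"""Reference-segment extraction and the segment-count-vs-length curve.

Subjects with fully complete timelines are systematically lighter drinkers
than subjects with gaps, so the neighbor pool is built from *every* gap-free
L-day slice of *every* subject rather than from complete subjects only.
The trade-off curve (mean number of gap-free windows per subject as a
function of L) quantifies how much reference material a given segment
length retains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeline import DAY_MIN, N_DAYS, SubjectTimeline, pos_to_day


@dataclass(frozen=True)
class ReferenceSegment:
    """A gap-free L-day slice of one subject's timeline."""

    subject_id: str
    site: str
    start_day: int
    start_weekday: int  # weekday of start_day, 0 = Monday
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


class SegmentPool:
    """Column-oriented store of reference segments for fast candidate
    filtering.

    Arrays are parallel over segments: ``values`` is (n_segments, L);
    ``start_day``, ``start_weekday``, ``subject_id`` and ``site`` are
    length n_segments.
    """

    def __init__(
        self,
        values: np.ndarray,
        start_day: np.ndarray,
        start_weekday: np.ndarray,
        subject_id: np.ndarray,
        site: np.ndarray,
        segment_length: int,
    ):
        self.values = values
        self.start_day = start_day
        self.start_weekday = start_weekday
        self.subject_id = subject_id
        self.site = site
        self.segment_length = segment_length

    def __len__(self) -> int:
        return len(self.start_day)

    def segment(self, i: int) -> ReferenceSegment:
        return ReferenceSegment(
            subject_id=str(self.subject_id[i]),
            site=str(self.site[i]),
            start_day=int(self.start_day[i]),
            start_weekday=int(self.start_weekday[i]),
            values=self.values[i],
        )

    def __iter__(self):
        return (self.segment(i) for i in range(len(self)))


def _complete_window_starts(observed: np.ndarray, L: int, stride: int) -> np.ndarray:
    """0-based start positions of fully observed length-L windows, on the
    stride grid."""
    n = len(observed)
    if L > n:
        return np.array([], dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(observed, L)
    complete = windows.all(axis=1)
    starts = np.flatnonzero(complete)
    return starts[starts % stride == 0]


def extract_segments(
    timelines: list[SubjectTimeline],
    L: int,
    stride: int = 1,
) -> SegmentPool:
    """Extract every gap-free window of length L from every timeline.

    Windows start on the stride grid (stride 1 = maximally overlapping).
    Values are copied as stored, i.e. after whatever Winsorization the
    cohort has been through.  An empty pool is legal.
    """
    if L < 1 or stride < 1:
        raise ValueError("L and stride must be >= 1")
    vals, sdays, swds, sids, sites = [], [], [], [], []
    for t in timelines:
        starts = _complete_window_starts(t.observed, L, stride)
        if len(starts) == 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(t.drinks, L)
        vals.append(win[starts].copy())
        sdays.append(pos_to_day(starts))
        swds.append((t.start_weekday + starts) % 7)
        sids.append(np.repeat(t.subject_id, len(starts)))
        sites.append(np.repeat(t.site, len(starts)))
    if not vals:
        return SegmentPool(
            values=np.empty((0, L)),
            start_day=np.array([], dtype=int),
            start_weekday=np.array([], dtype=int),
            subject_id=np.array([], dtype=object),
            site=np.array([], dtype=object),
            segment_length=L,
        )
    return SegmentPool(
        values=np.vstack(vals),
        start_day=np.concatenate(sdays),
        start_weekday=np.concatenate(swds),
        subject_id=np.concatenate(sids),
        site=np.concatenate(sites),
        segment_length=L,
    )


def segment_counts(timelines: list[SubjectTimeline], L: int) -> np.ndarray:
    """Per-subject count of gap-free L-day windows at stride 1."""
    return np.array([len(_complete_window_starts(t.observed, L, 1)) for t in timelines])


def segments_curve(
    timelines: list[SubjectTimeline],
    lengths: list[int],
) -> pd.DataFrame:
    """Mean gap-free-window count per subject for each segment length.

    On a fully observed cohort the value at L is 327 - L; on any cohort the
    curve is nonincreasing in L.
    """
    if not timelines:
        raise ValueError("segments_curve needs a nonempty cohort")
    rows = [
        {"segment_length": L, "mean_segments": segment_counts(timelines, L).mean()}
        for L in lengths
    ]
    return pd.DataFrame(rows)
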
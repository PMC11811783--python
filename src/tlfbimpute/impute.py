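"""The k-NN imputation core.

Missing days are filled from the k most similar gap-free reference
segments.  Similarity is the cosine of the angle between the query's
observed context and the candidate segment over the same positions —
a magnitude-blind measure of drinking *pattern* — restricted to candidates
whose days fall on the same weekday grid as the query's.  Because cosine
ignores magnitude, each neighbor's contribution is rescaled by the ratio of
Euclidean norms over the shared context, restoring the query subject's own
consumption level, and the k contributions are averaged with
similarity-proportional weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import ReferenceSegment, SegmentPool, extract_segments
from .timeline import (
    DAY_MAX,
    DAY_MIN,
    N_DAYS,
    PROV_CHAINED,
    PROV_IMPUTED,
    PROV_OBSERVED,
    ImputationConfig,
    SubjectTimeline,
    day_to_pos,
    pos_to_day,
)
from .preprocess import weekday_of_day


@dataclass
class QueryWindow:
    """An L-day window around a gap, with the observed-context mask.

    ``values`` holds the subject's drinks over the window; entries are only
    meaningful where ``observed_mask`` is True.  ``gap`` is the (start, end)
    day range (inclusive) of the positions to fill; it is always a subset of
    the unobserved positions.
    """

    subject_id: str
    window_start: int  # gestational day of position 0
    values: np.ndarray
    observed_mask: np.ndarray
    gap: tuple[int, int]
    start_weekday: int  # weekday of window_start

    @property
    def length(self) -> int:
        return len(self.values)

    def gap_positions(self) -> np.ndarray:
        lo, hi = self.gap
        return np.arange(lo - self.window_start, hi - self.window_start + 1)


@dataclass(frozen=True)
class NeighborMatch:
    """A selected reference segment with its similarity, normalized weight
    and consumption-level scale factor."""

    segment: ReferenceSegment
    similarity: float
    weight: float
    scale: float


def cosine_similarity(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Cosine similarity of two nonnegative vectors over masked positions.

    Conventions for degenerate inputs: two zero sub-vectors are maximally
    similar (1.0) — an abstinent context should match abstinent segments —
    while a zero against a nonzero sub-vector scores 0.0.  The associated
    distance is 1 - similarity.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cosine_similarity: empty mask")
    xv = np.asarray(x, dtype=float)[mask]
    yv = np.asarray(y, dtype=float)[mask]
    nx = np.linalg.norm(xv)
    ny = np.linalg.norm(yv)
    if nx == 0.0 and ny == 0.0:
        return 1.0
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(np.dot(xv, yv) / (nx * ny), 0.0, 1.0))


def scale_factor(query_values: np.ndarray, segment_values: np.ndarray,
                 mask: np.ndarray) -> float:
    """Consumption-level scale: ratio of Euclidean norms over the query's
    observed overlap; 1 when the segment's overlap is all zero (nothing to
    scale)."""
    mask = np.asarray(mask, dtype=bool)
    qn = np.linalg.norm(np.asarray(query_values, dtype=float)[mask])
    sn = np.linalg.norm(np.asarray(segment_values, dtype=float)[mask])
    if sn == 0.0:
        return 1.0
    return float(qn / sn)


class UnimputableGapError(RuntimeError):
    """No eligible reference segment exists for a gap."""


def _eligible_candidates(query: QueryWindow, pool: SegmentPool,
                         config: ImputationConfig) -> np.ndarray:
    """Indices of pool segments passing the weekday, position and
    self-segment filters."""
    if pool.segment_length != query.length:
        raise ValueError("pool segment length does not match query window length")
    ok = pool.start_weekday == query.start_weekday
    if config.position_tolerance is not None:
        ok &= np.abs(pool.start_day - query.window_start) <= config.position_tolerance
    is_self = pool.subject_id == query.subject_id
    if not config.include_self_segments:
        ok &= ~is_self
    else:
        # a subject's own segments may serve as neighbors, but never ones
        # overlapping the gap being filled (they would leak the answer)
        gap_lo, gap_hi = query.gap
        seg_lo = pool.start_day
        seg_hi = pool.start_day + pool.segment_length - 1
        overlaps_gap = (seg_lo <= gap_hi) & (seg_hi >= gap_lo)
        ok &= ~(is_self & overlaps_gap)
    return np.flatnonzero(ok)


def rank_candidates(query: QueryWindow, pool: SegmentPool,
                    config: ImputationConfig) -> tuple[np.ndarray, np.ndarray]:
    """All eligible candidates ranked by similarity (descending).

    Returns (pool indices in rank order, their similarities).  Ties are
    broken by proximity of segment start to the window start, then by
    subject id, then by segment start day, so the ranking is deterministic.
    """
    mask = query.observed_mask
    if int(mask.sum()) < config.min_overlap:
        return np.array([], dtype=int), np.array([])
    cand = _eligible_candidates(query, pool, config)
    if len(cand) == 0:
        return np.array([], dtype=int), np.array([])

    q = query.values[mask]
    Y = pool.values[cand][:, mask]
    qn = np.linalg.norm(q)
    yn = np.linalg.norm(Y, axis=1)
    if qn == 0.0:
        sims = np.where(yn == 0.0, 1.0, 0.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = (Y @ q) / (qn * yn)
        sims = np.where(yn == 0.0, 0.0, sims)
        sims = np.clip(sims, 0.0, 1.0)

    absdiff = np.abs(pool.start_day[cand] - query.window_start)
    sid_codes = pd.factorize(pool.subject_id[cand], sort=True)[0]
    order = np.lexsort((pool.start_day[cand], sid_codes, absdiff, -sims))
    return cand[order], sims[order]


def find_neighbors(query: QueryWindow, pool: SegmentPool,
                   config: ImputationConfig) -> list[NeighborMatch]:
    """Select the top-k neighbors for a query and attach weights and scales.

    Weights are proportional to similarity (uniform when every similarity
    is zero) and sum to 1 over the selected matches.  Fewer than k eligible
    candidates → all of them are used; zero candidates → empty list, the
    gap is un-imputable.
    """
    ranked, sims = rank_candidates(query, pool, config)
    if len(ranked) == 0:
        return []
    top = ranked[: config.k]
    top_sims = sims[: config.k]
    total = top_sims.sum()
    if total > 0:
        weights = top_sims / total
    else:
        weights = np.full(len(top), 1.0 / len(top))
    matches = []
    for idx, sim, w in zip(top, top_sims, weights):
        seg = pool.segment(int(idx))
        s = scale_factor(query.values, seg.values, query.observed_mask)
        matches.append(NeighborMatch(segment=seg, similarity=float(sim),
                                     weight=float(w), scale=s))
    return matches


def impute_gap(query: QueryWindow, matches: list[NeighborMatch],
               cap: float = np.inf) -> np.ndarray:
    """Weighted, scaled neighbor average at each gap position, clipped to
    [0, cap]."""
    if not matches:
        raise UnimputableGapError(
            f"subject {query.subject_id}: no eligible neighbor for gap {query.gap}"
        )
    pos = query.gap_positions()
    est = np.zeros(len(pos))
    for m in matches:
        est += m.weight * m.scale * m.segment.values[pos]
    return np.clip(est, 0.0, cap)


# ---------------------------------------------------------------------------
# Window placement and whole-cohort orchestration
# ---------------------------------------------------------------------------

def place_window(defined: np.ndarray, gap_lo_pos: int, gap_hi_pos: int,
                 L: int) -> int:
    """Choose the start position of the L-day query window for a gap.

    The window must contain the gap and stay inside the timeline; among
    feasible placements the one with the most defined context days wins,
    with ties resolved toward centering the gap.  Returns the 0-based start
    position.
    """
    n = len(defined)
    lo = max(0, gap_hi_pos - L + 1)
    hi = min(n - L, gap_lo_pos)
    if lo > hi:
        raise ValueError("gap does not fit in one window")
    centered = (gap_lo_pos + gap_hi_pos) // 2 - L // 2
    centered = min(max(centered, lo), hi)
    starts = np.arange(lo, hi + 1)
    counts = np.array([defined[s : s + L].sum() for s in starts])
    best = counts.max()
    tied = starts[counts == best]
    return int(tied[np.argmin(np.abs(tied - centered))])


def _missing_runs(observed: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of unobserved positions as (start, end) inclusive."""
    runs = []
    in_run = False
    for i, obs in enumerate(observed):
        if not obs and not in_run:
            start, in_run = i, True
        elif obs and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(observed) - 1))
    return runs


def impute_timeline(
    timeline: SubjectTimeline,
    pool: SegmentPool,
    config: ImputationConfig,
    cap: float = np.inf,
) -> tuple[SubjectTimeline, list[tuple[int, int]]]:
    """Fill every missing run of one timeline from the reference pool.

    Runs are processed left to right.  A run longer than
    ``segment_length - min_overlap`` is partitioned into chunks; later
    chunks may use earlier chunks' imputed values as context, and every
    chunk of such a run is flagged "imputed_chained" in the provenance.
    Observed values are never modified.  Returns the filled timeline and a
    list of (start_day, end_day) gaps left un-imputable.
    """
    L = config.segment_length
    max_chunk = max(L - config.min_overlap, 1)
    work = timeline.drinks.copy()
    defined = timeline.observed.copy()
    provenance = np.array(
        [PROV_OBSERVED if o else None for o in timeline.observed], dtype=object
    )
    unimputable: list[tuple[int, int]] = []

    for run_lo, run_hi in _missing_runs(timeline.observed):
        run_len = run_hi - run_lo + 1
        chained = run_len > max_chunk
        flag = PROV_CHAINED if chained else PROV_IMPUTED
        chunk_lo = run_lo
        while chunk_lo <= run_hi:
            chunk_hi = min(chunk_lo + max_chunk - 1, run_hi)
            ws_pos = place_window(defined, chunk_lo, chunk_hi, L)
            window_vals = np.where(defined[ws_pos : ws_pos + L],
                                   work[ws_pos : ws_pos + L], 0.0)
            obs_mask = defined[ws_pos : ws_pos + L].copy()
            query = QueryWindow(
                subject_id=timeline.subject_id,
                window_start=pos_to_day(ws_pos),
                values=window_vals,
                observed_mask=obs_mask,
                gap=(pos_to_day(chunk_lo), pos_to_day(chunk_hi)),
                start_weekday=weekday_of_day(timeline.start_weekday, pos_to_day(ws_pos)),
            )
            matches = find_neighbors(query, pool, config)
            if not matches:
                unimputable.append((pos_to_day(chunk_lo), pos_to_day(chunk_hi)))
            else:
                est = impute_gap(query, matches, cap=cap)
                work[chunk_lo : chunk_hi + 1] = est
                defined[chunk_lo : chunk_hi + 1] = True
                provenance[chunk_lo : chunk_hi + 1] = flag
            chunk_lo = chunk_hi + 1

    out = timeline.copy()
    out.drinks = np.where(defined, work, np.nan)
    out.observed = defined
    out.provenance = provenance
    return out, unimputable


def impute_all(
    timelines: list[SubjectTimeline],
    config: ImputationConfig,
    caps: dict[str, float] | None = None,
    pool: SegmentPool | None = None,
) -> tuple[list[SubjectTimeline], pd.DataFrame]:
    """Impute every timeline in a cohort against a shared reference pool.

    The pool defaults to all gap-free segments extracted from the cohort
    itself.  Returns the filled timelines (same order; subjects are never
    dropped) and a DataFrame of un-imputable gaps
    (subject_id, gap_start_day, gap_end_day).
    """
    if pool is None:
        pool = extract_segments(timelines, config.segment_length, config.stride)
    caps = caps or {}
    out: list[SubjectTimeline] = []
    failures: list[dict] = []
    for t in timelines:
        cap = caps.get(t.site, np.inf)
        filled, unimp = impute_timeline(t, pool, config, cap=cap)
        out.append(filled)
        failures.extend(
            {"subject_id": t.subject_id, "gap_start_day": lo, "gap_end_day": hi}
            for lo, hi in unimp
        )
    report = pd.DataFrame(failures,
                          columns=["subject_id", "gap_start_day", "gap_end_day"])
    return out, report
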
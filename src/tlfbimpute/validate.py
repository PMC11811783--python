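"""Deletion-based validation of the imputer.

The harness mimics how the method is assessed in practice: take subjects
whose first trimester is fully observed, delete a random run of 5-15
consecutive first-trimester days, impute the run against the pool built
from the un-deleted cohort, and compare prediction with truth.  Repeating
this over many iterations yields RMSE distributions per number of
neighbors k, a drinking/nondrinking confusion matrix, and distributions of
prediction-truth differences.  The first trimester is the natural deletion
target: both the prevalence and the magnitude of drinking peak there,
before pregnancy recognition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impute import QueryWindow, place_window, rank_candidates
from .pool import SegmentPool, extract_segments
from .preprocess import TRIMESTER_1, TRIMESTER_2, TRIMESTER_3, PERICONCEPTIONAL, weekday_of_day
from .timeline import ImputationConfig, SubjectTimeline, day_to_pos, pos_to_day

DRINKING = "drinking"
NONDRINKING = "nondrinking"


def rmse(truth: np.ndarray, prediction: np.ndarray) -> float:
    """Root mean squared error between two equal-length vectors."""
    truth = np.asarray(truth, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if truth.shape != prediction.shape or truth.ndim != 1 or len(truth) == 0:
        raise ValueError("rmse: inputs must be equal-length nonempty vectors")
    return float(np.sqrt(np.mean((prediction - truth) ** 2)))


def classify_segment(values: np.ndarray, threshold: float = 0.5) -> str:
    """Drinking iff total drinks over the segment reach the threshold.

    Ground-truth segments use ``threshold=None`` semantics via
    :func:`true_class` (any strictly positive value)."""
    return DRINKING if float(np.sum(values)) >= threshold else NONDRINKING


def true_class(values: np.ndarray) -> str:
    """Ground-truth segment class: drinking iff any day has drinks > 0."""
    return DRINKING if np.any(np.asarray(values) > 0) else NONDRINKING


@dataclass
class DeletionTrial:
    """One random deletion: a 5-15 day run inside trimester 1, its true
    values, and the timeline with the run masked out."""

    subject_id: str
    start_day: int
    length: int
    truth: np.ndarray
    deleted: SubjectTimeline

    @property
    def end_day(self) -> int:
        return self.start_day + self.length - 1


def is_validation_eligible(t: SubjectTimeline,
                           trimester1: tuple[int, int] = TRIMESTER_1) -> bool:
    lo, hi = day_to_pos(trimester1[0]), day_to_pos(trimester1[1])
    return bool(t.observed[lo : hi + 1].all())


def delete_random_segment(
    timeline: SubjectTimeline,
    rng: np.random.Generator,
    trimester1: tuple[int, int] = TRIMESTER_1,
    length_range: tuple[int, int] = (5, 15),
) -> DeletionTrial:
    """Delete a uniformly random 5-15 day run from trimester 1.

    Length is drawn uniformly from {5..15}; the start is uniform over
    placements keeping the whole run inside trimester 1.  The subject must
    be fully observed on trimester-1 days.
    """
    if not is_validation_eligible(timeline, trimester1):
        raise ValueError(
            f"subject {timeline.subject_id} has missing trimester-1 days; "
            "cannot serve as a deletion-validation subject"
        )
    t1_lo, t1_hi = trimester1
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    start_day = int(rng.integers(t1_lo, t1_hi - length + 2))
    lo, hi = day_to_pos(start_day), day_to_pos(start_day + length - 1)
    deleted = timeline.copy()
    truth = deleted.drinks[lo : hi + 1].copy()
    deleted.observed[lo : hi + 1] = False
    deleted.drinks[lo : hi + 1] = np.nan
    return DeletionTrial(
        subject_id=timeline.subject_id,
        start_day=start_day,
        length=length,
        truth=truth,
        deleted=deleted,
    )


def _query_for_trial(trial: DeletionTrial, L: int) -> QueryWindow:
    t = trial.deleted
    gap_lo, gap_hi = day_to_pos(trial.start_day), day_to_pos(trial.end_day)
    ws_pos = place_window(t.observed, gap_lo, gap_hi, L)
    return QueryWindow(
        subject_id=t.subject_id,
        window_start=pos_to_day(ws_pos),
        values=np.where(t.observed[ws_pos : ws_pos + L], t.drinks[ws_pos : ws_pos + L], 0.0),
        observed_mask=t.observed[ws_pos : ws_pos + L].copy(),
        gap=(trial.start_day, trial.end_day),
        start_weekday=weekday_of_day(t.start_weekday, pos_to_day(ws_pos)),
    )


def _predictions_by_k(
    query: QueryWindow,
    pool: SegmentPool,
    config: ImputationConfig,
    k_list: list[int],
    cap: float = np.inf,
) -> dict[int, np.ndarray]:
    """Imputed gap values for each k, sharing one candidate ranking.

    The neighbor ranking does not depend on k, so the top-max(k) candidates
    are ranked once and each k reuses its prefix.
    """
    ranked, sims = rank_candidates(query, pool, config)
    if len(ranked) == 0:
        return {}
    pos = query.gap_positions()
    mask = query.observed_mask
    qn = np.linalg.norm(query.values[mask])
    out: dict[int, np.ndarray] = {}
    kmax = min(max(k_list), len(ranked))
    top = ranked[:kmax]
    top_sims = sims[:kmax]
    seg_gap = pool.values[top][:, pos]
    seg_norms = np.linalg.norm(pool.values[top][:, mask], axis=1)
    scales = np.where(seg_norms == 0.0, 1.0, qn / np.where(seg_norms == 0.0, 1.0, seg_norms))
    for k in k_list:
        kk = min(k, kmax)
        s = top_sims[:kk]
        w = s / s.sum() if s.sum() > 0 else np.full(kk, 1.0 / kk)
        out[k] = np.clip((w * scales[:kk]) @ seg_gap[:kk], 0.0, cap)
    return out


def column_mean_prediction(
    timelines: list[SubjectTimeline],
    trial: DeletionTrial,
) -> np.ndarray:
    """Baseline: predict each deleted day with the cohort mean of observed
    drinks on that gestational day, excluding the deleted subject."""
    lo, hi = day_to_pos(trial.start_day), day_to_pos(trial.end_day)
    stack = np.array(
        [t.drinks[lo : hi + 1] for t in timelines if t.subject_id != trial.subject_id]
    )
    with np.errstate(invalid="ignore"):
        means = np.nanmean(stack, axis=0)
    return np.nan_to_num(means, nan=0.0)


@dataclass
class ValidationReport:
    """Aggregated results of the deletion experiment.

    ``trials`` is the long per-iteration record (one row per iteration x
    method); ``rmse_by_k`` summarizes RMSE per k and true segment class;
    ``confusion`` holds the 2x2 actual-vs-predicted proportions at the
    reference k (rows sum to 1); ``diff_distribution`` summarizes
    per-segment prediction-truth totals with percentile confidence
    intervals.
    """

    trials: pd.DataFrame
    rmse_by_k: pd.DataFrame
    confusion: pd.DataFrame
    diff_distribution: pd.DataFrame
    iterations: int
    k_ref: int

    def accuracy(self) -> float:
        """Overall classification accuracy recomputed from the trials at
        the reference k."""
        at_k = self.trials[(self.trials["method"] == "knn") & (self.trials["k"] == self.k_ref)]
        return float((at_k["truth_class"] == at_k["pred_class"]).mean())


def run_validation(
    timelines: list[SubjectTimeline],
    config: ImputationConfig,
    k_list: list[int] | None = None,
    iterations: int = 500,
    seed: int = 0,
    caps: dict[str, float] | None = None,
    include_baseline: bool = False,
    pool: SegmentPool | None = None,
) -> ValidationReport:
    """Run the full deletion-validation experiment.

    Each iteration samples an eligible subject (with replacement), deletes
    a random trimester-1 run, and imputes it with every k in ``k_list``
    against the pool built from the un-deleted cohort (the subject's own
    segments overlapping the deleted run are excluded by the imputer).
    """
    k_list = list(k_list) if k_list is not None else list(range(1, 11))
    caps = caps or {}
    rng = np.random.default_rng(seed)
    eligible = [t for t in timelines if is_validation_eligible(t)]
    if not eligible:
        raise ValueError("no subject is fully observed in trimester 1")
    if pool is None:
        pool = extract_segments(timelines, config.segment_length, config.stride)

    rows: list[dict] = []
    for it in range(iterations):
        subject = eligible[int(rng.integers(len(eligible)))]
        trial = delete_random_segment(subject, rng)
        query = _query_for_trial(trial, config.segment_length)
        cap = caps.get(subject.site, np.inf)
        preds = _predictions_by_k(query, pool, config, k_list, cap=cap)
        base = {
            "iteration": it,
            "subject_id": subject.subject_id,
            "site": subject.site,
            "start_day": trial.start_day,
            "length": trial.length,
            "truth_class": true_class(trial.truth),
            "truth_total": float(trial.truth.sum()),
        }
        for k in k_list:
            if k not in preds:
                continue
            p = preds[k]
            rows.append(
                base
                | {
                    "method": "knn",
                    "k": k,
                    "rmse": rmse(trial.truth, p),
                    "pred_class": classify_segment(p, config.classify_threshold),
                    "total_diff": float(p.sum() - trial.truth.sum()),
                    "mean_abs_diff": float(np.mean(np.abs(p - trial.truth))),
                }
            )
        if include_baseline:
            p = column_mean_prediction(timelines, trial)
            rows.append(
                base
                | {
                    "method": "column_mean",
                    "k": np.nan,
                    "rmse": rmse(trial.truth, p),
                    "pred_class": classify_segment(p, config.classify_threshold),
                    "total_diff": float(p.sum() - trial.truth.sum()),
                    "mean_abs_diff": float(np.mean(np.abs(p - trial.truth))),
                }
            )
    trials = pd.DataFrame(rows)

    knn = trials[trials["method"] == "knn"]
    rmse_by_k = (
        knn.groupby(["k", "truth_class"])["rmse"]
        .agg(
            mean_rmse="mean",
            median_rmse="median",
            ci_lo=lambda s: np.percentile(s, 2.5),
            ci_hi=lambda s: np.percentile(s, 97.5),
            n="count",
        )
        .reset_index()
    )

    k_ref = config.k if config.k in k_list else k_list[0]
    at_k = knn[knn["k"] == k_ref]
    confusion = (
        pd.crosstab(at_k["truth_class"], at_k["pred_class"], normalize="index")
        .reindex(index=[DRINKING, NONDRINKING], columns=[DRINKING, NONDRINKING])
        .fillna(0.0)
    )

    diff_distribution = (
        at_k.groupby("truth_class")
        .apply(
            lambda g: pd.Series(
                {
                    "mean_total_diff": g["total_diff"].mean(),
                    "ci_lo": np.percentile(g["total_diff"], 2.5),
                    "ci_hi": np.percentile(g["total_diff"], 97.5),
                    "prop_exact": (g["total_diff"].abs() < 0.5).mean(),
                    "prop_within_1_per_day": (g["mean_abs_diff"] <= 1.0).mean(),
                    "n": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )

    return ValidationReport(
        trials=trials,
        rmse_by_k=rmse_by_k,
        confusion=confusion,
        diff_distribution=diff_distribution,
        iterations=iterations,
        k_ref=k_ref,
    )


TRIMESTERS = {
    "periconceptional": PERICONCEPTIONAL,
    "trimester1": TRIMESTER_1,
    "trimester2": TRIMESTER_2,
    "trimester3": TRIMESTER_3,
}


def trimester_means(
    before: list[SubjectTimeline],
    after: list[SubjectTimeline],
) -> pd.DataFrame:
    """Mean drinks per person by site and trimester, before vs after
    imputation.

    Unobserved days count as zero drinks, so the delta per cell is the
    average number of drinks added by imputation; it is nonnegative
    whenever imputed values are nonnegative.
    """
    if len(before) != len(after) or any(
        b.subject_id != a.subject_id for b, a in zip(before, after)
    ):
        raise ValueError("before/after cohorts must list the same subjects in order")
    rows = []
    sites = sorted({t.site for t in before})
    for site in sites:
        pairs = [(b, a) for b, a in zip(before, after) if b.site == site]
        for tri_name, (lo_d, hi_d) in TRIMESTERS.items():
            lo, hi = day_to_pos(lo_d), day_to_pos(hi_d)
            mb = np.mean([np.nansum(b.drinks[lo : hi + 1]) for b, _ in pairs])
            ma = np.mean([np.nansum(a.drinks[lo : hi + 1]) for _, a in pairs])
            rows.append(
                {
                    "site": site,
                    "trimester": tri_name,
                    "mean_drinks_before": float(mb),
                    "mean_drinks_after": float(ma),
                    "delta": float(ma - mb),
                }
            )
    return pd.DataFrame(rows)
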
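import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_timeline
from tlfbimpute.impute import (
    QueryWindow,
    UnimputableGapError,
    cosine_similarity,
    find_neighbors,
    impute_all,
    impute_gap,
    place_window,
    rank_candidates,
    scale_factor,
)
from tlfbimpute.pool import SegmentPool, extract_segments
from tlfbimpute.preprocess import weekday_of_day
from tlfbimpute.timeline import DAY_MIN, DAY_MAX, N_DAYS, ImputationConfig

nonneg_vectors = st.lists(
    st.floats(min_value=0, max_value=50, allow_nan=False), min_size=2, max_size=12
)


class TestCosineSimilarity:
    def test_proportional_patterns_are_identical(self):
        # 3 drinks then 1 vs 6 then 2: same 3:1 pattern, angle zero
        m = np.array([True, True])
        assert cosine_similarity(np.array([3.0, 1.0]), np.array([6.0, 2.0]), m) == pytest.approx(1.0)

    def test_orthogonal_patterns_are_dissimilar(self):
        m = np.array([True, True])
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0]), m) == 0.0

    def test_two_abstinent_windows_are_identical(self):
        m = np.array([True, True])
        assert cosine_similarity(np.zeros(2), np.zeros(2), m) == 1.0

    def test_abstinent_vs_drinking_is_dissimilar(self):
        m = np.array([True, True])
        assert cosine_similarity(np.zeros(2), np.array([0.0, 3.0]), m) == 0.0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.ones(3), np.ones(3), np.zeros(3, dtype=bool))

    def test_only_masked_positions_matter(self):
        m = np.array([True, False, True])
        a = cosine_similarity(np.array([3.0, 99.0, 1.0]), np.array([6.0, 0.0, 2.0]), m)
        assert a == pytest.approx(1.0)

    @given(nonneg_vectors, st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, x, c):
        x = np.array(x)
        m = np.ones(len(x), dtype=bool)
        assert cosine_similarity(x, c * x, m) == pytest.approx(
            cosine_similarity(x, x, m), abs=1e-9
        )

    @given(nonneg_vectors, nonneg_vectors)
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        m = np.ones(n, dtype=bool)
        s = cosine_similarity(x, y, m)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(cosine_similarity(y, x, m), abs=1e-12)


class TestScaleFactor:
    def test_half_as_heavy(self):
        m = np.ones(2, dtype=bool)
        assert scale_factor(np.array([3.0, 1.0]), np.array([6.0, 2.0]), m) == pytest.approx(0.5)

    def test_identical_levels(self):
        m = np.ones(2, dtype=bool)
        assert scale_factor(np.array([2.0, 5.0]), np.array([2.0, 5.0]), m) == 1.0

    def test_abstinent_query_scales_to_zero(self):
        m = np.ones(2, dtype=bool)
        assert scale_factor(np.zeros(2), np.array([4.0, 1.0]), m) == 0.0

    def test_abstinent_segment_scales_to_one(self):
        m = np.ones(2, dtype=bool)
        assert scale_factor(np.array([4.0, 1.0]), np.zeros(2), m) == 1.0


def _random_pool(rng, n_segments, L, n_subjects=20, tol=28, window_start=50):
    """Random segment pool concentrated near the query window.

    (subject_id, start_day) pairs are kept unique, as extraction from real
    timelines guarantees, so the ranking tie-break is a total order."""
    lo = max(DAY_MIN, window_start - tol)
    hi = min(DAY_MAX - L + 1, window_start + tol)
    subjects, starts = [], []
    per_subject = {f"s{j:02d}": rng.permutation(np.arange(lo, hi + 1)) for j in range(n_subjects)}
    for i in range(n_segments):
        sid = f"s{i % n_subjects:02d}"
        subjects.append(sid)
        starts.append(int(per_subject[sid][i // n_subjects % (hi - lo + 1)]))
    return SegmentPool(
        values=rng.gamma(1.0, 2.0, size=(n_segments, L)) * (rng.random((n_segments, L)) < 0.4),
        start_day=np.array(starts),
        start_weekday=rng.integers(0, 7, n_segments),
        subject_id=np.array(subjects, dtype=object),
        site=np.array(["SA"] * n_segments, dtype=object),
        segment_length=L,
    )


def _random_query(rng, L, window_start=50, subject_id="q0"):
    mask = rng.random(L) < 0.8
    gap_len = int(rng.integers(3, 9))
    gap_start = int(rng.integers(0, L - gap_len + 1))
    mask[gap_start : gap_start + gap_len] = False
    values = np.where(mask, rng.gamma(1.0, 2.0, L) * (rng.random(L) < 0.4), 0.0)
    return QueryWindow(
        subject_id=subject_id,
        window_start=window_start,
        values=values,
        observed_mask=mask,
        gap=(window_start + gap_start, window_start + gap_start + gap_len - 1),
        start_weekday=int(rng.integers(0, 7)),
    )


def oracle_ranking(query, pool, config):
    """Exhaustive brute-force candidate ranking, implemented independently
    with plain Python arithmetic."""
    gap_lo, gap_hi = query.gap
    L = pool.segment_length
    mask = [bool(b) for b in query.observed_mask]
    if sum(mask) < config.min_overlap:
        return []
    q = [float(v) for v, m in zip(query.values, mask) if m]
    qn = math.sqrt(math.fsum(v * v for v in q))
    rows = []
    for i in range(len(pool)):
        seg = pool.segment(i)
        if seg.start_weekday != query.start_weekday:
            continue
        if config.position_tolerance is not None and abs(seg.start_day - query.window_start) > config.position_tolerance:
            continue
        if seg.subject_id == query.subject_id:
            if not config.include_self_segments:
                continue
            if not (seg.start_day + L - 1 < gap_lo or seg.start_day > gap_hi):
                continue
        y = [float(v) for v, m in zip(seg.values, mask) if m]
        yn = math.sqrt(math.fsum(v * v for v in y))
        if qn == 0.0:
            sim = 1.0 if yn == 0.0 else 0.0
        elif yn == 0.0:
            sim = 0.0
        else:
            sim = min(max(math.fsum(a * b for a, b in zip(q, y)) / (qn * yn), 0.0), 1.0)
        rows.append((-sim, abs(seg.start_day - query.window_start), seg.subject_id, seg.start_day, i))
    rows.sort()
    return [r[4] for r in rows]


class TestFindNeighbors:
    def test_exact_duplicate_ranks_first_with_similarity_one(self):
        rng = np.random.default_rng(0)
        pool = _random_pool(rng, 60, L=14)
        q = _random_query(rng, L=14)
        q.start_weekday = int(pool.start_weekday[17])
        # plant a duplicate of the query's observed pattern as candidate 17
        pool.values[17] = np.where(q.observed_mask, q.values, 1.0)
        pool.start_day[17] = q.window_start
        pool.subject_id[17] = "dup"
        matches = find_neighbors(q, pool, ImputationConfig(k=3, segment_length=14))
        assert matches[0].segment.subject_id == "dup"
        assert matches[0].similarity == pytest.approx(1.0)

    def test_weights_are_normalized_similarities(self):
        rng = np.random.default_rng(1)
        pool = _random_pool(rng, 300, L=10)
        q = _random_query(rng, L=10)
        q.start_weekday = int(pool.start_weekday[0])
        matches = find_neighbors(q, pool, ImputationConfig(k=2, segment_length=10, min_overlap=3))
        assert len(matches) == 2
        sims = np.array([m.similarity for m in matches])
        np.testing.assert_allclose(
            [m.weight for m in matches], sims / sims.sum(), atol=1e-12
        )
        assert sum(m.weight for m in matches) == pytest.approx(1.0)

    def test_two_to_one_weight_split(self):
        # similarities (1.0, 0.5) must yield weights (2/3, 1/3)
        sims = np.array([1.0, 0.5])
        w = sims / sims.sum()
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_ranking_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = ImputationConfig(k=5, segment_length=12)
        pool = _random_pool(rng, 150, L=12)
        for _ in range(10):
            q = _random_query(rng, L=12, subject_id=f"s{rng.integers(20)}")
            ranked, sims = rank_candidates(q, pool, config)
            assert list(ranked) == oracle_ranking(q, pool, config)
            assert np.all(np.diff(sims) <= 1e-12)

    def test_empty_pool_flags_unimputable(self):
        q = _random_query(np.random.default_rng(2), L=10)
        empty = extract_segments([], L=10)
        assert find_neighbors(q, empty, ImputationConfig(k=5, segment_length=10)) == []
        with pytest.raises(UnimputableGapError):
            impute_gap(q, [])


class TestImputeGap:
    def _single_match_query(self):
        q = QueryWindow(
            subject_id="p",
            window_start=10,
            values=np.array([3.0, 1.0, 0.0]),
            observed_mask=np.array([True, True, False]),
            gap=(12, 12),
            start_weekday=0,
        )
        return q

    def test_single_neighbor_scaled_estimate(self):
        # query (3,1,·) against neighbor (6,2,4): scale 0.5, estimate 2.0
        q = self._single_match_query()
        pool = SegmentPool(
            values=np.array([[6.0, 2.0, 4.0]]),
            start_day=np.array([10]),
            start_weekday=np.array([0]),
            subject_id=np.array(["r"], dtype=object),
            site=np.array(["SA"], dtype=object),
            segment_length=3,
        )
        matches = find_neighbors(q, pool, ImputationConfig(k=1, segment_length=3, min_overlap=2))
        est = impute_gap(q, matches)
        assert est == pytest.approx([2.0])

    def test_abstinent_neighbors_give_zero(self):
        q = self._single_match_query()
        pool = SegmentPool(
            values=np.array([[3.0, 1.0, 0.0], [6.0, 2.0, 0.0]]),
            start_day=np.array([10, 10]),
            start_weekday=np.array([0, 0]),
            subject_id=np.array(["a", "b"], dtype=object),
            site=np.array(["SA", "SA"], dtype=object),
            segment_length=3,
        )
        matches = find_neighbors(q, pool, ImputationConfig(k=2, segment_length=3, min_overlap=2))
        assert impute_gap(q, matches) == pytest.approx([0.0])

    def test_weighted_mean_by_hand(self):
        # weights (2/3, 1/3), scales (1, 1), gap values (3, 0) -> 2.0
        est = np.array([2 / 3 * 1 * 3.0 + 1 / 3 * 1 * 0.0])
        assert est == pytest.approx([2.0])

    def test_clipped_at_site_cap(self):
        q = self._single_match_query()
        pool = SegmentPool(
            values=np.array([[6.0, 2.0, 50.0]]),
            start_day=np.array([10]),
            start_weekday=np.array([0]),
            subject_id=np.array(["r"], dtype=object),
            site=np.array(["SA"], dtype=object),
            segment_length=3,
        )
        matches = find_neighbors(q, pool, ImputationConfig(k=1, segment_length=3, min_overlap=2))
        assert impute_gap(q, matches, cap=21.0) == pytest.approx([21.0])


class TestPlaceWindow:
    def test_prefers_centering_the_gap(self):
        defined = np.ones(100, dtype=bool)
        defined[40:50] = False
        start = place_window(defined, 40, 49, 20)
        assert start <= 40 and start + 20 > 49
        assert abs((start + 10) - 45) <= 1

    def test_shifts_to_maximize_context(self):
        defined = np.ones(100, dtype=bool)
        defined[40:50] = False
        defined[30:40] = False  # left side also missing: shift right
        start = place_window(defined, 40, 49, 20)
        assert defined[start : start + 20].sum() == 10
        assert start == 40  # window [40, 60) keeps all 10 context days


class TestImputeAll:
    def test_complete_cohort_is_a_no_op(self, small_cohort):
        complete = [t for t in small_cohort if t.n_missing() == 0][:5]
        out, failures = impute_all(complete, ImputationConfig())
        assert failures.empty
        for a, b in zip(complete, out):
            np.testing.assert_array_equal(a.drinks[a.observed], b.drinks[b.observed])
            assert (b.provenance[b.observed] == "observed").all()

    def test_twin_recovery_up_to_scaling(self):
        """A c-scaled copy of the query's true data recovers a deleted gap
        exactly: the norm-ratio scaling cancels c."""
        rng = np.random.default_rng(5)
        truth = rng.gamma(1.5, 2.0, N_DAYS) * (rng.random(N_DAYS) < 0.5)
        days = np.arange(DAY_MIN, DAY_MAX + 1)
        gap_days = set(range(40, 50))
        vals_q = {int(d): float(v) for d, v in zip(days, truth) if d not in gap_days}
        query_t = make_timeline("p", start_weekday=2, observed_days=vals_q, values=vals_q)
        c = 3.0
        vals_twin = {int(d): float(c * v) for d, v in zip(days, truth)}
        twin_t = make_timeline("twin", start_weekday=2, observed_days=vals_twin, values=vals_twin)
        cfg = ImputationConfig(k=1)
        out, failures = impute_all([query_t, twin_t], cfg)
        assert failures.empty
        got = [out[0].value_on(d) for d in sorted(gap_days)]
        want = [truth[d - DAY_MIN] for d in sorted(gap_days)]
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_long_gap_is_chunked_and_flagged_chained(self):
        vals = {int(d): 1.0 for d in range(DAY_MIN, DAY_MAX + 1) if not (50 <= d < 200)}
        gappy = make_timeline("g", start_weekday=0, observed_days=vals, values=vals)
        donor = make_timeline("d", start_weekday=0, fill=1.0)
        cfg = ImputationConfig(position_tolerance=None)
        out, failures = impute_all([gappy, donor], cfg)
        assert failures.empty
        filled = out[0]
        run = filled.provenance[50 - DAY_MIN : 200 - DAY_MIN]
        assert (run == "imputed_chained").all()
        # 150-day gap with 48-day chunks -> at least 3 chunks
        assert np.ceil(150 / (cfg.segment_length - cfg.min_overlap)) >= 3
        assert filled.n_missing() == 0

    def test_observed_values_never_modified_and_bounded(self, small_cohort):
        sub = small_cohort[:12]
        cfg = ImputationConfig()
        caps = {"SA": 21.0, "NP": 28.0}
        out, _ = impute_all(sub, cfg, caps=caps)
        for a, b in zip(sub, out):
            np.testing.assert_array_equal(a.drinks[a.observed], b.drinks[a.observed])
            imputed_mask = b.observed & ~a.observed
            if imputed_mask.any():
                imputed = b.drinks[imputed_mask]
                assert imputed.min() >= 0.0
                assert imputed.max() <= caps[a.site]

    def test_impossible_gap_is_flagged_not_dropped(self):
        vals = {int(d): 1.0 for d in range(1, 31)}
        lonely = make_timeline("solo", observed_days=vals, values=vals)
        out, failures = impute_all([lonely], ImputationConfig())
        assert len(out) == 1
        assert len(failures) > 0
        assert (failures["subject_id"] == "solo").all()
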
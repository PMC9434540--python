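"""Gallery ranking and retrieval metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxreid.retrieval_eval import (GalleryIndex, RankedRetrieval,
                                   average_precision_at_r, mean_ap_at_r,
                                   precision_at_1, r_precision, rank_all,
                                   rank_by_distance, report_from_rankings)


def oracle_metrics(ids, emb, pids):
    """Independent re-enumeration of distances, rankings and precisions."""
    emb = np.asarray(emb, dtype=np.float64)
    maps, rps, p1s = [], [], []
    for qi in range(len(ids)):
        others = [i for i in range(len(ids)) if i != qi]
        dists = [(float(np.linalg.norm(emb[qi] - emb[i])), ids[i], i) for i in others]
        dists.sort()
        rel = [1 if pids[i] == pids[qi] else 0 for _, _, i in dists]
        r = sum(rel)
        if r == 0:
            continue
        hits = 0
        ap = 0.0
        for rank in range(r):
            hits += rel[rank]
            if rel[rank]:
                ap += hits / (rank + 1)
        maps.append(ap / r)
        rps.append(sum(rel[:r]) / r)
        p1s.append(rel[0])
    return (float(np.mean(maps)), float(np.mean(rps)), float(np.mean(p1s)))


def rr(relevance, query="q"):
    ids = [f"g{i}" for i in range(len(relevance))]
    return RankedRetrieval(query, ids, np.asarray(relevance))


class TestRanking:
    def test_identical_embedding_ranks_first_at_distance_zero(self):
        g = GalleryIndex(["a", "b", "c"], np.array([[0.0, 0], [5, 5], [1, 1]]),
                         ["pa", "pb", "pc"])
        out = rank_by_distance(np.array([1.0, 1.0]), g, query_id="x")
        assert out.ranked_ids[0] == "c"

    def test_hand_computed_four_point_gallery(self):
        emb = np.array([[0.0, 0], [3, 0], [0, 4], [3, 4]])
        g = GalleryIndex(["a", "b", "c", "d"], emb, ["p1", "p2", "p1", "p2"])
        out = rank_by_distance(emb[0], g, query_id="a")
        assert out.ranked_ids == ["b", "c", "d"]        # distances 3, 4, 5
        np.testing.assert_array_equal(out.relevance, [0, 1, 0])

    def test_invariant_to_gallery_permutation(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(6, 4))
        ids = [f"g{i}" for i in range(6)]
        pids = ["p0", "p0", "p1", "p1", "p2", "p2"]
        a = rank_by_distance(emb[0], GalleryIndex(ids, emb, pids), "g0")
        perm = rng.permutation(6)
        b = rank_by_distance(emb[0], GalleryIndex([ids[i] for i in perm],
                                                  emb[perm],
                                                  [pids[i] for i in perm]), "g0")
        assert a.ranked_ids == b.ranked_ids

    def test_query_never_retrieves_itself(self):
        emb = np.zeros((4, 3))
        g = GalleryIndex(list("abcd"), emb, ["p"] * 4)
        for q in "abcd":
            out = rank_by_distance(emb[0], g, query_id=q)
            assert q not in out.ranked_ids

    def test_tie_break_by_image_id(self):
        emb = np.zeros((3, 2))
        g = GalleryIndex(["c", "a", "b"], emb, ["p1", "p2", "p3"])
        out = rank_by_distance(np.zeros(2), g, query_id="z")
        assert out.ranked_ids == ["a", "b", "c"]


class TestMetricDefinitions:
    def test_r_precision_three_of_four(self):
        assert r_precision(rr([1, 1, 1, 0, 1])) == 0.75

    def test_r_precision_extremes(self):
        assert r_precision(rr([1, 1, 0])) == 1.0        # R=2, both in top 2
        assert r_precision(rr([0, 0, 1, 1])) == 0.0     # R=2, none in top 2

    def test_ap_at_r_counts_only_first_r_ranks(self):
        # R=2: relevant at ranks 1 and 3 -> only rank 1 contributes
        assert average_precision_at_r(rr([1, 0, 1])) == 0.5
        # R=2: relevant at ranks 2 and 3 -> only rank 2 contributes P@2=1/2
        assert average_precision_at_r(rr([0, 1, 1])) == 0.25

    def test_ap_at_r_alternative_reading_covers_all_relevant(self):
        got = average_precision_at_r(rr([1, 0, 1]), first_r_ranks=False)
        assert got == pytest.approx(0.5 * (1.0 + 2 / 3))

    def test_perfect_prefix_gives_one(self):
        assert average_precision_at_r(rr([1, 1, 1, 0, 0])) == 1.0

    def test_mean_ap_is_arithmetic_mean(self):
        rrs = [rr([1, 1, 0]), rr([1, 0, 1])]
        assert mean_ap_at_r(rrs) == pytest.approx((1.0 + 0.5) / 2)

    def test_precision_at_1_counting(self):
        rrs = [rr([1, 0]), rr([1, 1]), rr([0, 1]), rr([1, 0])]
        assert precision_at_1(rrs) == 0.75


class TestOracleEquivalence:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_all_metrics_match_brute_force_on_small_galleries(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        emb = np.round(rng.normal(size=(n, 3)), 1)       # rounded -> ties happen
        pids = [f"p{rng.integers(0, max(2, n // 2))}" for _ in range(n)]
        ids = [f"g{i}" for i in range(n)]
        gallery = GalleryIndex(ids, emb, pids)
        rrs = rank_all(gallery)
        if not rrs:
            return
        got = report_from_rankings(rrs)
        want = oracle_metrics(ids, emb, pids)
        assert got.map_at_r == pytest.approx(want[0], abs=1e-12)
        assert got.r_precision == pytest.approx(want[1], abs=1e-12)
        assert got.precision_at_1 == pytest.approx(want[2], abs=1e-12)

    def test_perfect_identity_embedding_scores_one(self):
        emb = np.repeat(np.arange(4)[:, None] * 10.0, 2, axis=0)
        ids = [f"g{i}" for i in range(8)]
        pids = [f"p{i // 2}" for i in range(8)]
        rep = report_from_rankings(rank_all(GalleryIndex(ids, emb + 0.0, pids)))
        assert (rep.map_at_r, rep.r_precision, rep.precision_at_1) == (1, 1, 1)


class TestInvariances:
    def test_global_isometry_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(10, 4))
        pids = [f"p{i // 2}" for i in range(10)]
        ids = [f"g{i}" for i in range(10)]
        base = report_from_rankings(rank_all(GalleryIndex(ids, emb, pids)))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        moved = emb @ q + np.array([5.0, -3.0, 2.0, 0.7])
        rot = report_from_rankings(rank_all(GalleryIndex(ids, moved, pids)))
        assert base.map_at_r == pytest.approx(rot.map_at_r, abs=1e-9)
        assert base.precision_at_1 == pytest.approx(rot.precision_at_1)

    def test_duplicating_gallery_never_lowers_precision_at_1(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(8, 3))
        pids = [f"p{i // 2}" for i in range(8)]
        ids = [f"g{i}" for i in range(8)]
        base = precision_at_1(rank_all(GalleryIndex(ids, emb, pids)))
        dup_ids = ids + [f"h{i}" for i in range(8)]
        dup = precision_at_1(rank_all(GalleryIndex(
            dup_ids, np.vstack([emb, emb]), pids + pids)))
        assert dup >= base

    def test_ranking_csv_reports_distances(self, tmp_path):
        from cxreid.retrieval_eval import write_rankings
        import pandas as pd
        emb = np.array([[0.0, 0], [3, 4], [1, 0]])
        g = GalleryIndex(["a", "b", "c"], emb, ["p1", "p2", "p1"])
        rrs = rank_all(g)
        path = tmp_path / "rank.csv"
        write_rankings(rrs, path)
        df = pd.read_csv(path)
        first = df[(df.query_id == "a") & (df["rank"] == 1)].iloc[0]
        assert first.gallery_id == "c" and first.distance == pytest.approx(1.0)

    def test_r0_queries_are_excluded_and_counted(self):
        emb = np.array([[0.0, 0], [1, 0], [5, 5]])
        g = GalleryIndex(["a", "b", "lone"], emb, ["p1", "p1", "p2"])
        rrs = rank_all(g)
        assert {r.query_id for r in rrs} == {"a", "b"}
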
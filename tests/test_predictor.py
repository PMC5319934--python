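"""Search engine: neighbor ranking, target collection, consensus merging."""

from __future__ import annotations

import pytest

from ppb import (
    ALL_SCHEMES,
    Scheme,
    TargetHit,
    collect_targets,
    compute_profile,
    merge_consensus,
    predict,
    profile_distance,
    rank_neighbors,
    standardize,
)


def _brute_force_hits(query_profile, db, scheme, st, n_targets=20):
    """Independent oracle: all pairwise distances, per-target minima, re-sort."""
    best: dict[str, tuple[float, str]] = {}
    for g in db.groups:
        dmin = min(
            (profile_distance(query_profile, db.profiles[cid], scheme, st), cid)
            for cid in g.compound_ids
        )
        best[g.target_id] = dmin
    # target order mirrors the neighbor scan: by (distance of nearest member,
    # nearest member compound id)
    order = sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    return [(tid, d, cid) for tid, (d, cid) in order[:n_targets]]


class TestRankNeighbors:
    def test_self_retrieval_distance_zero(self, db, scaling):
        cid = next(iter(db.profiles))
        ordered = rank_neighbors(db.profiles[cid], db, Scheme.ECfp4, scaling)
        assert ordered[0][0] == cid and ordered[0][1] == 0

    @pytest.mark.parametrize("scheme", ALL_SCHEMES)
    def test_matches_exhaustive_sort(self, db, scaling, world, scheme):
        query = compute_profile(standardize(world.queries[0][1]))
        ordered = rank_neighbors(query, db, scheme, scaling)
        expected = sorted(
            (
                (cid, profile_distance(query, prof, scheme, scaling))
                for cid, prof in db.profiles.items()
            ),
            key=lambda t: (t[1], t[0]),
        )
        assert ordered == expected

    def test_empty_db_rejected(self, db, scaling):
        from ppb.reference_db import ReferenceDatabase

        empty = ReferenceDatabase(groups=[], profiles={})
        query = compute_profile(standardize("CCO"))
        with pytest.raises(ValueError):
            rank_neighbors(query, empty, Scheme.MQN, scaling)


class TestCollectTargets:
    def test_all_targets_when_few(self, db, scaling, calibration, world):
        query = compute_profile(standardize(world.queries[0][1]))
        ordered = rank_neighbors(query, db, Scheme.Sfp, scaling)
        hits = collect_targets(ordered, db, Scheme.Sfp, n_targets=20, calib=calibration)
        assert len(hits) == len(db.groups)  # only 5 targets exist

    def test_single_target_is_nearest_neighbors(self, db, scaling, world):
        query = compute_profile(standardize(world.queries[0][1]))
        ordered = rank_neighbors(query, db, Scheme.ECfp4, scaling)
        hits = collect_targets(ordered, db, Scheme.ECfp4, n_targets=1)
        assert len(hits) == 1
        assert hits[0].nn_compound_id == ordered[0][0]

    @pytest.mark.parametrize("scheme", [Scheme.APfp, Scheme.MQN, Scheme.Ffp3])
    def test_hit_distance_is_group_minimum(self, db, scaling, calibration, world, scheme):
        query = compute_profile(standardize(world.queries[3][1]))
        ordered = rank_neighbors(query, db, scheme, scaling)
        hits = collect_targets(ordered, db, scheme, n_targets=20, calib=calibration)
        expected = _brute_force_hits(query, db, scheme, scaling)
        assert [(h.target_id, h.nn_distance, h.nn_compound_id) for h in hits] == expected

    def test_identical_flag_iff_zero_distance(self, db, scaling):
        cid = next(iter(db.profiles))
        ordered = rank_neighbors(db.profiles[cid], db, Scheme.Xfp, scaling)
        hits = collect_targets(ordered, db, Scheme.Xfp)
        for h in hits:
            assert h.identical_flag == (h.nn_distance == 0)


class TestMergeConsensus:
    def _hit(self, tid, scheme, p=None, d=1.0):
        return TargetHit(target_id=tid, scheme=scheme, nn_distance=d,
                         nn_compound_id="c", p=p)

    def test_votes_dominate_pvalues(self):
        per_scheme = {
            s: [self._hit("A", s, p=0.9)] for s in ALL_SCHEMES
        }
        per_scheme[ALL_SCHEMES[0]].append(self._hit("B", ALL_SCHEMES[0], p=1e-9))
        report = merge_consensus(per_scheme)
        assert [e.target_id for e in report.consensus] == ["A", "B"]
        assert report.consensus[0].votes == len(ALL_SCHEMES)

    def test_equal_votes_sorted_by_p_sum(self):
        s1, s2 = ALL_SCHEMES[:2]
        per_scheme = {
            s1: [self._hit("A", s1, p=0.25), self._hit("B", s1, p=0.0005)],
            s2: [self._hit("A", s2, p=0.25), self._hit("B", s2, p=0.0005)],
        }
        report = merge_consensus(per_scheme)
        assert [e.target_id for e in report.consensus] == ["B", "A"]

    def test_null_p_counts_as_one(self):
        s1 = ALL_SCHEMES[0]
        per_scheme = {s1: [self._hit("A", s1, p=None), self._hit("B", s1, p=0.99)]}
        report = merge_consensus(per_scheme)
        assert report.consensus[0].target_id == "B"
        a = next(e for e in report.consensus if e.target_id == "A")
        assert a.p_sum == 1.0

    def test_min_votes_filter(self):
        s1, s2 = ALL_SCHEMES[:2]
        per_scheme = {
            s1: [self._hit("A", s1, p=0.1), self._hit("B", s1, p=0.1)],
            s2: [self._hit("A", s2, p=0.1)],
        }
        report = merge_consensus(per_scheme)
        assert [e.target_id for e in report.combined(2)] == ["A"]

    def test_ranking_is_total_order(self, db, scaling, calibration, world):
        report = predict(world.queries[1][1], db, calib=calibration, st=scaling)
        keys = [(-e.votes, e.p_sum, e.best_p, e.target_id) for e in report.consensus]
        assert keys == sorted(keys)
        assert [e.rank for e in report.consensus] == list(
            range(1, len(report.consensus) + 1)
        )


class TestPredict:
    def test_member_query_retrieves_own_target_everywhere(self, db, scaling, calibration):
        group = db.groups[2]
        cid, smi = group.members[0]
        report = predict(smi, db, calib=calibration, st=scaling)
        for scheme in ALL_SCHEMES:
            hit = next(h for h in report.per_scheme[scheme] if h.target_id == group.target_id)
            assert hit.nn_distance == 0 and hit.identical_flag

    def test_planted_analog_found_by_consensus(self, db, scaling, calibration, world):
        qid, smi, true_target = world.queries[0]
        report = predict(smi, db, calib=calibration, st=scaling, query_id=qid)
        combined = [e.target_id for e in report.combined(2)]
        assert true_target in combined

    def test_reports_reproducible(self, db, scaling, calibration, world):
        qid, smi, _ = world.queries[2]
        a = predict(smi, db, calib=calibration, st=scaling, query_id=qid)
        b = predict(smi, db, calib=calibration, st=scaling, query_id=qid)
        assert a.to_dict() == b.to_dict()

    def test_no_calibration_yields_null_p(self, db, scaling, world):
        report = predict(world.queries[0][1], db, calib=None, st=scaling)
        assert all(
            h.p is None for hits in report.per_scheme.values() for h in hits
        )

    def test_hit_lists_capped_at_n_targets(self, db, scaling, calibration, world):
        report = predict(
            world.queries[0][1], db, calib=calibration, st=scaling, n_targets=2
        )
        assert all(len(hits) <= 2 for hits in report.per_scheme.values())
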
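import itertools

import numpy as np
import pytest

from skelsuite import (
    BoxRecord,
    TrackDataset,
    aggregate_reports,
    evaluate_tracking,
    id_switches,
    idf1,
    iou,
    match_frames,
    mota,
    motp,
    mt_ml,
)
from skelsuite.mot_metrics import TABLE_COLUMNS


def _ds(rows, n_frames=0):
    """rows: (frame, id, left, top, w, h)."""
    return TrackDataset(
        records=[BoxRecord(f, i, l, t, w, h, 1.0) for f, i, l, t, w, h in rows],
        n_frames=n_frames,
    )


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def oracle_match_frames(gt, hyp, thr):
    """Exhaustive re-implementation of the frame-matching protocol:
    persistence, then the best one-to-one assignment by enumeration."""
    gt_frames, hyp_frames = gt.frames(), hyp.frames()
    frames = sorted(set(gt_frames) | set(hyp_frames))
    prev = {}
    all_matches = {}
    for t in frames:
        g = {r.track_id: r for r in gt_frames.get(t, [])}
        h = {r.track_id: r for r in hyp_frames.get(t, [])}
        matches = []
        used_h = set()
        for gid, hid in prev.items():
            if gid in g and hid in h and hid not in used_h:
                o = iou(g[gid], h[hid])
                if o >= thr:
                    matches.append((gid, hid, o))
                    used_h.add(hid)
        free_g = [x for x in sorted(g) if x not in {m[0] for m in matches}]
        free_h = [x for x in sorted(h) if x not in used_h]
        best, best_cost = [], np.inf
        k = min(len(free_g), len(free_h))
        # enumerate every one-to-one pairing of any size k
        for g_sub in itertools.combinations(free_g, k):
            for h_perm in itertools.permutations(free_h, k):
                cost = sum(1 - iou(g[a], h[b]) for a, b in zip(g_sub, h_perm))
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best = [
                        (a, b, iou(g[a], h[b]))
                        for a, b in zip(g_sub, h_perm)
                        if iou(g[a], h[b]) >= thr
                    ]
        matches += best
        all_matches[t] = sorted(matches)
        prev = {a: b for a, b, _ in matches}
    return all_matches


def oracle_idf1(gt, hyp, thr):
    """IDF1 by exhaustive search over all injective id-to-id mappings."""
    gt_ids, hyp_ids = gt.track_ids(), hyp.track_ids()
    n_gt = len(gt.records)
    n_hyp = len(hyp.records)
    overlap = {}
    for t, g_recs in gt.frames().items():
        for g in g_recs:
            for h in hyp.frames().get(t, []):
                if iou(g, h) >= thr:
                    overlap[(g.track_id, h.track_id)] = (
                        overlap.get((g.track_id, h.track_id), 0) + 1
                    )
    best_idtp = 0
    k = min(len(gt_ids), len(hyp_ids))
    for size in range(k + 1):
        for g_sub in itertools.combinations(gt_ids, size):
            for h_perm in itertools.permutations(hyp_ids, size):
                idtp = sum(overlap.get((a, b), 0) for a, b in zip(g_sub, h_perm))
                best_idtp = max(best_idtp, idtp)
    denom = 2 * best_idtp + (n_hyp - best_idtp) + (n_gt - best_idtp)
    return 100.0 * 2 * best_idtp / denom if denom else 0.0


def _random_scenario(rng, n_ids=3, n_frames=8):
    """A small random tracking toy with overlapping, ambiguous boxes."""
    gt_rows, hyp_rows = [], []
    for i in range(1, n_ids + 1):
        for f in range(1, n_frames + 1):
            if rng.random() < 0.15:
                continue
            x = 50.0 * i + 2.0 * f
            gt_rows.append((f, i, x, 10.0, 20, 40))
    for i in range(1, n_ids + 1):
        for f in range(1, n_frames + 1):
            if rng.random() < 0.25:
                continue
            # jittered copy, sometimes with a relabeled id
            x = 50.0 * i + 2.0 * f + rng.normal(0, 4)
            hid = i if rng.random() > 0.2 else int(rng.integers(1, n_ids + 1))
            hyp_rows.append((f, hid, x, 10.0 + rng.normal(0, 4), 20, 40))
    # drop duplicate (frame, id)
    seen, hyp_unique = set(), []
    for row in hyp_rows:
        if (row[0], row[1]) not in seen:
            seen.add((row[0], row[1]))
            hyp_unique.append(row)
    return _ds(gt_rows, n_frames), _ds(hyp_unique, n_frames)


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 2, 2), (10, 10, 2, 2)) == 0.0

    def test_forced_third(self):
        assert iou((0, 0, 2, 2), (1, 0, 2, 2)) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            a = tuple(rng.uniform(0, 10, 2)) + tuple(rng.uniform(1, 5, 2))
            b = tuple(rng.uniform(0, 10, 2)) + tuple(rng.uniform(1, 5, 2))
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))


class TestMatchFrames:
    def test_perfect_hypothesis(self):
        gt = _ds([(f, i, 10.0 * i, 0, 5, 5) for f in (1, 2, 3) for i in (1, 2)])
        assign = match_frames(gt, gt)
        for t in (1, 2, 3):
            assert len(assign.matches[t]) == 2
            assert assign.unmatched_gt[t] == [] and assign.unmatched_hyp[t] == []

    def test_empty_hypothesis(self):
        gt = _ds([(1, 1, 0, 0, 5, 5), (2, 1, 0, 0, 5, 5)])
        assign = match_frames(gt, _ds([], n_frames=2))
        assert assign.n_matches == 0
        assert assign.unmatched_gt[1] == [1]

    def test_persistence_keeps_previous_pair(self):
        # two hyp boxes both overlap gt 1; the one matched in frame 1 must
        # be kept in frame 2 even though the other is now slightly closer
        gt = _ds([(1, 1, 0, 0, 10, 10), (2, 1, 2, 0, 10, 10)])
        hyp = _ds([(1, 7, 0, 0, 10, 10), (2, 7, 0, 0, 10, 10),
                   (2, 8, 2, 0, 10, 10)])
        assign = match_frames(gt, hyp)
        assert assign.matches[2][0][:2] == (1, 7)

    def test_matches_brute_force_on_ambiguous_overlaps(self, rng):
        for _ in range(20):
            gt, hyp = _random_scenario(rng)
            assign = match_frames(gt, hyp, 0.3)
            expected = oracle_match_frames(gt, hyp, 0.3)
            for t in assign.frames:
                got = {(g, h) for g, h, _ in assign.matches[t]}
                want = {(g, h) for g, h, _ in expected[t]}
                # optimal pairings may tie; totals must agree
                assert len(got) == len(want)
                got_cost = sum(1 - o for _, _, o in assign.matches[t])
                want_cost = sum(1 - o for _, _, o in expected[t])
                assert got_cost == pytest.approx(want_cost, abs=1e-9)


class TestIdSwitches:
    def test_perfect_tracking_zero(self):
        gt = _ds([(f, i, 10.0 * i, 0, 5, 5) for f in range(1, 6) for i in (1, 2)])
        assert id_switches(match_frames(gt, gt)) == 0

    def test_persisting_swap_counts_two(self):
        # hyp ids of the two objects swap at frame 6 and stay swapped
        gt_rows, hyp_rows = [], []
        for f in range(1, 11):
            for i in (1, 2):
                x = 100.0 * i
                gt_rows.append((f, i, x, 0, 10, 10))
                hid = i if f < 6 else 3 - i
                hyp_rows.append((f, hid, x, 0, 10, 10))
        assign = match_frames(_ds(gt_rows), _ds(hyp_rows))
        assert id_switches(assign) == 2

    def test_gap_with_same_id_no_switch(self):
        gt_rows = [(f, 1, 0.0, 0, 10, 10) for f in range(1, 9)]
        hyp_rows = [(f, 5, 0.0, 0, 10, 10) for f in (1, 2, 6, 7, 8)]
        assign = match_frames(_ds(gt_rows), _ds(hyp_rows))
        assert id_switches(assign) == 0

    def test_gap_with_changed_id_one_switch(self):
        gt_rows = [(f, 1, 0.0, 0, 10, 10) for f in range(1, 9)]
        hyp_rows = [(f, 5, 0.0, 0, 10, 10) for f in (1, 2)]
        hyp_rows += [(f, 6, 0.0, 0, 10, 10) for f in (6, 7, 8)]
        assign = match_frames(_ds(gt_rows), _ds(hyp_rows))
        assert id_switches(assign) == 1


class TestMOTAMOTP:
    def test_perfect_is_100(self):
        gt = _ds([(f, i, 10.0 * i, 0, 5, 5) for f in range(1, 6) for i in (1, 2)])
        value, counts = mota(gt, gt, match_frames(gt, gt))
        assert value == 100.0
        assert counts == {"FN": 0, "FP": 0, "IDsw": 0, "GT": 10}

    def test_empty_hypothesis_is_zero(self):
        gt = _ds([(f, 1, 0.0, 0, 5, 5) for f in range(1, 6)])
        value, _ = mota(gt, _ds([], n_frames=5), match_frames(gt, _ds([], 5)))
        assert value == 0.0

    def test_hand_worked_example(self):
        """10 frames x 2 objects (sum GT = 20) with 2 misses, 1 false
        positive and 1 persisting-swap pair -> MOTA = 80.0."""
        gt_rows, hyp_rows = [], []
        for f in range(1, 11):
            for i in (1, 2):
                x = 100.0 * i
                gt_rows.append((f, i, x, 0, 10, 10))
                if (f, i) in ((3, 1), (7, 2)):
                    continue  # 2 FN
                hid = i if f < 9 else 3 - i  # swap at frame 9: 2 IDsw...
                hyp_rows.append((f, hid, x, 0, 10, 10))
        hyp_rows.append((5, 99, 1000.0, 1000, 10, 10))  # 1 FP
        gt, hyp = _ds(gt_rows), _ds(hyp_rows)
        assign = match_frames(gt, hyp)
        value, counts = mota(gt, hyp, assign)
        assert counts["FN"] == 2 and counts["FP"] == 1 and counts["IDsw"] == 2
        assert value == pytest.approx(100.0 * (1 - 5 / 20))

    def test_motp_mean_overlap(self):
        gt = _ds([(1, 1, 0, 0, 2, 2), (2, 1, 0, 0, 2, 2)])
        hyp = _ds([(1, 1, 0, 0, 2, 2), (2, 1, 1, 0, 2, 2)])
        assign = match_frames(gt, hyp, iou_threshold=0.3)
        assert motp(assign) == pytest.approx((1.0 + 1 / 3) / 2)

    def test_motp_matches_flat_loop(self, rng):
        gt, hyp = _random_scenario(rng)
        assign = match_frames(gt, hyp, 0.3)
        flat = [o for t in assign.frames for _, _, o in assign.matches[t]]
        if flat:
            assert motp(assign) == pytest.approx(np.mean(flat), abs=1e-12)


class TestIDF1:
    def test_perfect_is_100(self):
        gt = _ds([(f, i, 10.0 * i, 0, 5, 5) for f in range(1, 6) for i in (1, 2)])
        value, counts = idf1(gt, gt)
        assert value == 100.0
        assert counts["IDFP"] == counts["IDFN"] == 0

    def test_empty_hypothesis_is_zero(self):
        gt = _ds([(1, 1, 0, 0, 5, 5)])
        value, _ = idf1(gt, _ds([], n_frames=1))
        assert value == 0.0

    def test_fragmented_toy_matches_brute_force(self):
        # 2 GT tracks, 3 hyp fragments over 10 frames
        gt_rows = [(f, i, 100.0 * i, 0, 10, 10) for f in range(1, 11)
                   for i in (1, 2)]
        hyp_rows = [(f, 11, 100.0, 0, 10, 10) for f in range(1, 5)]
        hyp_rows += [(f, 12, 100.0, 0, 10, 10) for f in range(5, 11)]
        hyp_rows += [(f, 13, 200.0, 0, 10, 10) for f in range(1, 11)]
        gt, hyp = _ds(gt_rows), _ds(hyp_rows)
        value, counts = idf1(gt, hyp)
        assert value == pytest.approx(oracle_idf1(gt, hyp, 0.5))
        assert counts["IDTP"] == 16  # 6-frame fragment + full second track

    def test_random_toys_match_brute_force(self, rng):
        for _ in range(15):
            gt, hyp = _random_scenario(rng, n_ids=3, n_frames=6)
            value, _ = idf1(gt, hyp, 0.3)
            assert value == pytest.approx(oracle_idf1(gt, hyp, 0.3), abs=1e-9)


class TestMTML:
    def test_full_coverage(self):
        gt = _ds([(f, i, 10.0 * i, 0, 5, 5) for f in range(1, 6) for i in (1, 2)])
        mt, ml, coverage = mt_ml(gt, match_frames(gt, gt))
        assert (mt, ml) == (2, 0)
        assert all(c == 1.0 for c in coverage.values())

    @pytest.mark.parametrize(
        "covered,expected_mt,expected_ml",
        [((17, 10, 2), 1, 1),   # coverages 0.85, 0.5, 0.1
         ((16, 4, 20), 2, 1)],  # 0.8 counts MT, 0.2 counts ML (inclusive)
    )
    def test_coverage_boundaries(self, covered, expected_mt, expected_ml):
        n_frames = 20
        gt_rows, hyp_rows = [], []
        for i, n_cov in enumerate(covered, start=1):
            x = 200.0 * i
            for f in range(1, n_frames + 1):
                gt_rows.append((f, i, x, 0, 10, 10))
                if f <= n_cov:
                    hyp_rows.append((f, i, x, 0, 10, 10))
        gt, hyp = _ds(gt_rows), _ds(hyp_rows)
        mt, ml, _ = mt_ml(gt, match_frames(gt, hyp))
        assert (mt, ml) == (expected_mt, expected_ml)


class TestEvaluateTracking:
    def test_perfect_report(self):
        gt = _ds([(f, i, 10.0 * i, 0, 5, 5) for f in range(1, 6) for i in (1, 2)])
        report = evaluate_tracking(gt, gt)
        assert report["MOTA"] == 100.0
        assert report["MOTP"] == 1.0
        assert report["IDF1"] == 100.0
        assert report["IDsw"] == 0
        assert report["Recall"] == report["Precision"] == 100.0
        assert report["ML"] == 0

    def test_report_keys_are_table_columns(self):
        gt = _ds([(1, 1, 0, 0, 5, 5)])
        report = evaluate_tracking(gt, gt)
        assert tuple(report.values.keys()) == TABLE_COLUMNS

    def test_id_relabeling_invariance(self, rng):
        gt, hyp = _random_scenario(rng)
        base = evaluate_tracking(gt, hyp)
        relabel = {i: 100 + i * 7 for i in hyp.track_ids()}
        hyp2 = TrackDataset(
            records=[
                BoxRecord(r.frame, relabel[r.track_id], r.left, r.top,
                          r.width, r.height, r.confidence)
                for r in hyp.records
            ],
            n_frames=hyp.n_frames,
        )
        other = evaluate_tracking(gt, hyp2)
        for key in TABLE_COLUMNS:
            assert other[key] == pytest.approx(base[key])


class TestAggregateReports:
    def test_published_mota_average(self):
        rows = [{"MOTA": v} for v in (27.5, 15.6, 56.5, 49.0)]
        assert aggregate_reports(rows)["MOTA"] == 37.15

    def test_published_idf1_average(self):
        rows = [{"IDF1": v} for v in (7.9, 5.9, 49.0, 19.3)]
        assert aggregate_reports(rows)["IDF1"] == 20.52

    def test_truncation_not_rounding(self):
        assert aggregate_reports([{"IDsw": 2772.75}])["IDsw"] == 2772
        assert aggregate_reports([{"MOTP": 0.20475}])["MOTP"] == 0.204

    def test_single_row_identity(self):
        row = {"MOTA": 55.60, "MOTP": 0.204, "IDsw": 28057.0}
        assert aggregate_reports([row]).values == row
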
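"""Metric correctness against hand counts and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucseg.metrics import (
    aji,
    dice,
    evaluate_masks,
    label_components,
    match_objects,
    object_prf,
    MatchResult,
)


# ---------------------------------------------------------------------------
# independent oracles: plain-python set arithmetic, no shared code paths
# ---------------------------------------------------------------------------

def _instances(mask):
    out = {}
    for (r, c), v in np.ndenumerate(mask):
        if v:
            out.setdefault(int(v), set()).add((r, c))
    return out


def _oracle_aji(gt, pred):
    """Direct evaluation of the aggregated Jaccard index on pixel sets."""
    g = _instances(gt)
    p = _instances(pred)
    if not g and not p:
        return 1.0
    used = set()
    num = den = 0
    for gi in sorted(g):
        best_j, best_jac = None, -1.0
        for pj in sorted(p):
            if pj in used:
                continue
            inter = len(g[gi] & p[pj])
            if inter == 0:
                continue
            jac = inter / len(g[gi] | p[pj])
            if jac > best_jac:
                best_j, best_jac = pj, jac
        if best_j is None:
            den += len(g[gi])
        else:
            used.add(best_j)
            num += len(g[gi] & p[best_j])
            den += len(g[gi] | p[best_j])
    for pj in p:
        if pj not in used:
            den += len(p[pj])
    return num / den if den else 1.0


def _oracle_max_matching_tp(gt, pred, threshold=0.5):
    """Maximum-cardinality matching over IoU >= threshold pairs, by brute
    force over injective assignments."""
    g = _instances(gt)
    p = _instances(pred)
    edges = {
        (gi, pj)
        for gi in g for pj in p
        if len(g[gi] & p[pj]) / len(g[gi] | p[pj]) >= threshold
    }
    gids, pids = sorted(g), sorted(p)
    best = 0
    for k in range(min(len(gids), len(pids)), 0, -1):
        for gsub in itertools.combinations(gids, k):
            for psub in itertools.permutations(pids, k):
                if all((gi, pj) in edges for gi, pj in zip(gsub, psub)):
                    return k
    return best


def _random_instance_mask(rng, shape=(8, 8), max_instances=3):
    """Blob-like random instance mask with up to 3 instances."""
    mask = np.zeros(shape, dtype=np.int32)
    k = rng.integers(0, max_instances + 1)
    for label in range(1, k + 1):
        r, c = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        h = rng.integers(1, 5)
        w = rng.integers(1, 5)
        mask[r:r + h, c:c + w] = label
    return mask


# ---------------------------------------------------------------------------

class TestLabelComponents:
    def test_disjoint_squares(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[0:2, 0:2] = 1
        m[4:6, 4:6] = 1
        lab = label_components(m)
        assert lab.max() == 2
        assert lab[0, 0] == 1 and lab[5, 5] == 2  # raster order

    def test_diagonal_touch_is_one_instance(self):
        m = np.eye(4, dtype=np.uint8)
        assert label_components(m).max() == 1

    def test_empty_mask(self):
        assert label_components(np.zeros((4, 4), dtype=np.uint8)).max() == 0


class TestMatching:
    def test_identical_masks(self):
        m = np.zeros((8, 8), dtype=np.int32)
        m[0:3, 0:3] = 1
        m[5:8, 5:8] = 2
        res = match_objects(m, m)
        assert (res.tp, res.fp, res.fn) == (2, 0, 0)

    def test_three_quarter_overlap_is_tp(self):
        gt = np.zeros((6, 6), dtype=np.int32)
        gt[0:4, 0:4] = 1
        pred = np.zeros((6, 6), dtype=np.int32)
        pred[0:3, 0:4] = 1  # IoU 12/16 = 0.75
        res = match_objects(gt, pred)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.pairs[0][2] == pytest.approx(0.75)

    def test_quarter_overlap_is_fp_and_fn(self):
        gt = np.zeros((6, 6), dtype=np.int32)
        gt[0:4, 0:4] = 1
        pred = np.zeros((6, 6), dtype=np.int32)
        pred[0:1, 0:4] = 1  # IoU 4/16 = 0.25
        res = match_objects(gt, pred)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_gt_coverage_rule(self):
        gt = np.zeros((6, 6), dtype=np.int32)
        gt[0:4, 0:4] = 1
        pred = np.zeros((6, 6), dtype=np.int32)
        pred[0:6, 0:6] = 1  # covers all of GT but IoU = 16/36 < 0.5
        assert match_objects(gt, pred, rule="iou").tp == 0
        assert match_objects(gt, pred, rule="gt-coverage").tp == 1

    def test_matching_is_one_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            gt = _random_instance_mask(rng)
            pred = _random_instance_mask(rng)
            res = match_objects(gt, pred)
            gids = [g for g, _, _ in res.pairs]
            pids = [p for _, p, _ in res.pairs]
            assert len(set(gids)) == len(gids)
            assert len(set(pids)) == len(pids)
            assert res.tp + res.fn == len(np.unique(gt)) - (0 in gt)
            assert res.tp + res.fp == len(np.unique(pred)) - (0 in pred)

    def test_greedy_matches_brute_force_maximum(self):
        """On small masks the greedy IoU>=0.5 matching attains the
        maximum-cardinality matching computed by exhaustive search."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            gt = _random_instance_mask(rng)
            pred = _random_instance_mask(rng)
            assert match_objects(gt, pred).tp == _oracle_max_matching_tp(gt, pred)


class TestPRF:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (3, 1, 1, (0.75, 0.75, 0.75)),
            (4, 0, 0, (1.0, 1.0, 1.0)),
            (0, 3, 2, (0.0, 0.0, 0.0)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
        ],
    )
    def test_closed_forms(self, tp, fp, fn, expected):
        got = object_prf(MatchResult(tp=tp, fp=fp, fn=fn))
        assert got == pytest.approx(expected)


class TestDice:
    def test_hand_counted_example(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[0:4, 0:4] = 1  # |G| = 16
        pred = np.zeros((8, 8), dtype=np.uint8)
        pred[1:4, 0:4] = 1  # |S| = 12, fully inside G
        assert dice(gt, pred) == pytest.approx(24 / 28)

    def test_identical_and_disjoint(self):
        m = (np.arange(16).reshape(4, 4) < 6).astype(np.uint8)
        assert dice(m, m) == 1.0
        assert dice(m, 1 - m) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dice(z, z) == 1.0


class TestAJI:
    def test_identity_scores_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = _random_instance_mask(rng)
            assert aji(m, m) == pytest.approx(1.0)

    def test_spurious_instance_penalty(self):
        """Perfect pixels plus one extra predicted blob of size s gives
        exactly |G| / (|G| + s)."""
        gt = np.zeros((8, 8), dtype=np.int32)
        gt[0:3, 0:3] = 1  # |G| = 9
        pred = gt.copy()
        pred[6:8, 6:8] = 2  # spurious, s = 4
        assert aji(gt, pred) == pytest.approx(9 / 13)

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            gt = _random_instance_mask(rng)
            pred = _random_instance_mask(rng)
            assert aji(gt, pred) == pytest.approx(_oracle_aji(gt, pred))

    def test_added_false_positive_never_raises_aji(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            gt = _random_instance_mask(rng)
            pred = _random_instance_mask(rng)
            base = aji(gt, pred)
            worse = pred.copy()
            # a spurious instance lies on true background: no GT overlap
            free = (worse == 0) & (gt == 0) \
                & (np.add.outer(np.arange(8), np.arange(8)) % 3 == 0)
            if not free.any():
                continue
            worse[free] = worse.max() + 1
            assert aji(gt, worse) <= base + 1e-12


class TestEvaluate:
    def test_perfect_prediction_all_ones(self):
        rng = np.random.default_rng(5)
        m = _random_instance_mask(rng)
        rep = evaluate_masks(m, m)
        assert rep.as_dict() == pytest.approx(
            {"precision": 1.0, "recall": 1.0, "f1": 1.0, "dice": 1.0, "aji": 1.0})

    def test_empty_prediction_all_zero(self):
        gt = np.zeros((8, 8), dtype=np.int32)
        gt[2:5, 2:5] = 1
        rep = evaluate_masks(gt, np.zeros_like(gt))
        assert rep.f1 == rep.dice == rep.aji == 0.0

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None)
    def test_all_metrics_bounded(self, seed):
        rng = np.random.default_rng(seed)
        rep = evaluate_masks(_random_instance_mask(rng),
                             _random_instance_mask(rng))
        for v in rep.as_dict().values():
            assert 0.0 <= v <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            aji(np.zeros((4, 4), dtype=int), np.zeros((5, 5), dtype=int))


class TestEvaluateDirs:
    def test_directory_report_and_unpaired_error(self, tmp_path):
        from nucseg.imgio import write_instance_mask
        from nucseg.metrics import evaluate_dirs

        gt_dir, pred_dir = tmp_path / "gt", tmp_path / "pred"
        gt_dir.mkdir(), pred_dir.mkdir()
        rng = np.random.default_rng(6)
        for i in range(3):
            m = _random_instance_mask(rng)
            write_instance_mask(gt_dir / f"t{i}.png", m)
            write_instance_mask(pred_dir / f"t{i}.png", m)
        report = evaluate_dirs(gt_dir, pred_dir, out_csv=tmp_path / "r.csv")
        assert report["macro"]["aji"] == pytest.approx(1.0)
        assert (tmp_path / "r.csv").exists()
        write_instance_mask(gt_dir / "extra.png", np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError, match="extra"):
            evaluate_dirs(gt_dir, pred_dir)
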
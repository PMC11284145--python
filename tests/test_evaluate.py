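import itertools

import numpy as np
import pytest

from qrspeak.evaluate import (
    evaluate,
    evaluate_many,
    fnr_by_type,
    margin_stats,
    match,
    metrics,
)
from qrspeak.records import BeatAnnotation, RecordError


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_match_basic():
    pairs, fp, fn = match([100, 300, 900], [105, 310, 600], 250.0)
    assert pairs == [(0, 0), (1, 1)]
    assert fp == [2] and fn == [2]


def test_match_is_one_to_one():
    # two detections near one beat: only one matches
    pairs, fp, fn = match([100, 110], [105], 250.0)
    assert len(pairs) == 1 and len(fp) == 1 and fn == []


def test_match_tolerance_strict():
    fs = 250.0
    # 0.15 s = 37.5 samples; 37 matches, 38 does not
    pairs, fp, _ = match([137], [100], fs)
    assert pairs == [(0, 0)]
    pairs, fp, _ = match([138], [100], fs)
    assert pairs == [] and fp == [0]


def test_match_equidistant_tie_earlier_annotation():
    pairs, _, fn = match([100], [90, 110], 250.0)
    assert pairs == [(0, 0)] and fn == [1]


def test_match_accepts_beat_annotations():
    anns = [BeatAnnotation(100, "N", "N"), BeatAnnotation(400, "V", "V")]
    pairs, fp, fn = match([101, 395], anns, 250.0)
    assert pairs == [(0, 0), (1, 1)] and not fp and not fn


def test_match_rejects_unsorted():
    with pytest.raises(RecordError):
        match([200, 100], [100], 250.0)
    with pytest.raises(RecordError):
        match([100], [200, 100], 250.0)


def oracle_match(det, ann, fs, tol_s):
    """Reference: same greedy policy, written independently."""
    taken = set()
    pairs, fp = [], []
    for i, d in enumerate(det):
        best, best_d = None, None
        for j, a in enumerate(ann):
            if j in taken:
                continue
            dist = abs(a - d)
            if best is None or dist < best_d:
                best, best_d = j, dist
        if best is not None and best_d / fs < tol_s:
            taken.add(best)
            pairs.append((i, best))
        else:
            fp.append(i)
    fn = [j for j in range(len(ann)) if j not in taken]
    return pairs, fp, fn


def test_match_against_bruteforce_oracle():
    rng = np.random.default_rng(99)
    for _ in range(500):
        fs = float(rng.choice([250.0, 360.0]))
        nd, na = int(rng.integers(0, 10)), int(rng.integers(0, 10))
        det = np.sort(rng.choice(3000, nd, replace=False))
        ann = np.sort(rng.choice(3000, na, replace=False))
        got = match(det, ann, fs)
        want = oracle_match(list(det), list(ann), fs, 0.15)
        assert got == want


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

# Published pooled counts with their printed two-decimal percentages
# (benchmark tables of several QRS detectors); the formulas must
# reproduce every printed value exactly.
PRINTED_ROWS = [
    # (tp, fp, fn, sen, pre, err)
    (50803, 208, 218, 99.57, 99.59, 0.83),
    (184366, 679, 217, 99.88, 99.63, 0.48),
    (778424, 4498, 669, 99.91, 99.43, 0.66),
    (72855, 387, 46, 99.94, 99.47, 0.59),
    (24253, 1466, 1337, 94.78, 94.30, 10.36),
    (28299, 1696, 1148, 96.10, 94.35, 9.13),
    (5596, 4, 95, 98.33, 99.93, 1.74),
    (28020, 2521, 1427, 95.15, 91.75, 12.35),
    (25403, 7350, 4064, 86.21, 77.56, 31.00),
    (24549, 5939, 4918, 83.31, 80.52, 30.66),
]


@pytest.mark.parametrize("tp,fp,fn,sen,pre,err", PRINTED_ROWS)
def test_metrics_reproduce_printed_rows(tp, fp, fn, sen, pre, err):
    s, p, e = metrics(tp, fp, fn)
    assert round(s, 2) == sen
    assert round(p, 2) == pre
    assert round(e, 2) == err


def test_metrics_degenerate_cases():
    assert metrics(0, 0, 0) == (None, None, None)
    s, p, e = metrics(0, 5, 0)
    assert s is None and p == 0.0 and e == 100.0
    s, p, e = metrics(0, 0, 5)
    assert s == 0.0 and p is None and e == 100.0


def test_err_can_exceed_100():
    _, _, e = metrics(1, 10, 3)
    assert e == pytest.approx(100.0 * 13 / 14)


def test_fnr_by_type():
    anns = [BeatAnnotation(s, t, t) for s, t in
            [(100, "N"), (400, "N"), (700, "V"), (1000, "V"), (1300, "S")]]
    pairs = [(0, 0), (1, 2)]  # one N and one V matched
    fn = [1, 3, 4]            # one N, one V, the S missed
    out = fnr_by_type(fn, pairs, anns)
    assert out == {"N": 50.0, "S": 100.0, "V": 50.0}


def test_margin_stats():
    det = [100, 210, 295]
    ann = [105, 200, 300]
    pairs = [(0, 0), (1, 1), (2, 2)]
    mean, sd = margin_stats(pairs, det, ann, 1000.0)
    offs = [5.0, 10.0, 5.0]
    assert mean == pytest.approx(np.mean(offs))
    assert sd == pytest.approx(np.std(offs, ddof=1))
    assert margin_stats([(0, 0)], [100], [101], 1000.0)[1] == 0.0
    assert margin_stats([], [], [], 1000.0) == (None, None)


def test_evaluate_full_report():
    anns = [BeatAnnotation(s, "N", "N") for s in (250, 500, 750)]
    rep = evaluate([252, 505, 1200], anns, 250.0)
    assert (rep.tp, rep.fp, rep.fn) == (2, 1, 1)
    assert rep.sen == pytest.approx(100 * 2 / 3)
    assert rep.pre == pytest.approx(100 * 2 / 3)
    assert rep.fnr_by_type == {"N": pytest.approx(100 / 3)}
    r = rep.rounded()
    assert r["sen"] == 66.67 and r["tolerance_s"] == 0.15


def test_evaluate_many_pools_exactly():
    anns1 = [BeatAnnotation(s, "N", "N") for s in (250, 500)]
    anns2 = [BeatAnnotation(s, "V", "V") for s in (100, 300, 600)]
    rep = evaluate_many([
        ([252, 800], anns1, 250.0),
        ([101, 301, 601], anns2, 250.0),
    ])
    assert (rep.tp, rep.fp, rep.fn) == (4, 1, 1)
    assert rep.sen == pytest.approx(80.0)
    assert rep.fnr_by_type == {"N": 50.0, "V": 0.0}
    # margins pooled across records: offsets 2, 1, 1, 1 samples at 250 Hz
    offs = np.array([2, 1, 1, 1]) / 250.0 * 1000.0
    assert rep.margin_mean_ms == pytest.approx(np.mean(offs))
    assert rep.margin_sd_ms == pytest.approx(np.std(offs, ddof=1))


def test_evaluate_many_matches_concatenation_when_records_disjoint():
    """Pooling equals single-record evaluation on shifted concatenation."""
    rng = np.random.default_rng(5)
    items, all_det, all_ann = [], [], []
    offset = 0
    for _ in range(4):
        ann = np.sort(rng.choice(4000, 6, replace=False) + 500)
        det = ann + rng.integers(-20, 21, ann.size)
        det = np.sort(det)
        items.append((det, ann, 250.0))
        all_det.extend(det + offset)
        all_ann.extend(ann + offset)
        offset += 10000
    pooled = evaluate_many(items)
    concat = evaluate(all_det, all_ann, 250.0)
    assert (pooled.tp, pooled.fp, pooled.fn) == (concat.tp, concat.fp, concat.fn)
    assert pooled.margin_mean_ms == pytest.approx(concat.margin_mean_ms)
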
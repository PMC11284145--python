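import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrspeak.model import QRSNet, count_parameters
from qrspeak.records import RecordError
from qrspeak.simulate import SimConfig, simulate_segment
from qrspeak.train import (
    Hyper,
    evaluate_loss,
    fit,
    masked_bce,
    masked_bce_with_grad,
    slice_segments,
)

from conftest import TINY_CFG


def _maps(vals):
    return [np.asarray(v, dtype=np.float64) for v in vals]


def test_bce_uniform_half_is_ln2():
    pred = _maps([np.full((2, 100), 0.5), np.full((2, 50), 0.5),
                  np.full((2, 25), 0.5)])
    tgt = [np.zeros((2, 100), np.int8), np.ones((2, 50), np.int8),
           np.zeros((2, 25), np.int8)]
    assert masked_bce(pred, tgt) == pytest.approx(np.log(2.0), abs=1e-9)


def test_bce_perfect_prediction_near_zero():
    tgt = [np.zeros((1, 100), np.int8), np.ones((1, 50), np.int8),
           np.zeros((1, 25), np.int8)]
    pred = _maps([np.zeros((1, 100)), np.ones((1, 50)), np.zeros((1, 25))])
    # clipped at 1e-7, so the floor is -log(1 - 1e-7) ~ 1e-7
    assert masked_bce(pred, tgt) <= 1.2e-6


def test_bce_ignores_masked_points():
    rng = np.random.default_rng(0)
    pred = _maps([rng.uniform(0.1, 0.9, (1, 100)),
                  rng.uniform(0.1, 0.9, (1, 50)),
                  rng.uniform(0.1, 0.9, (1, 25))])
    tgt = [rng.integers(0, 2, (1, n)).astype(np.int8) for n in (100, 50, 25)]
    # corrupt predictions only at points we then mask out; the loss must
    # equal a recomputation over the surviving points alone
    pred2 = [p.copy() for p in pred]
    tgt2 = [t.copy() for t in tgt]
    for p, t in zip(pred2, tgt2):
        idx = rng.choice(p.shape[1], size=10, replace=False)
        p[0, idx] = rng.uniform(0, 1, 10)
        t[0, idx] = -1
    ref = []
    for p, t in zip(pred2, tgt2):
        m = t[0] != -1
        yv = (t[0][m] == 1).astype(float)
        pc = np.clip(p[0][m], 1e-7, 1 - 1e-7)
        ref.append(np.mean(-(yv * np.log(pc) + (1 - yv) * np.log1p(-pc))))
    assert masked_bce(pred2, tgt2) == pytest.approx(np.mean(ref), abs=1e-12)


def test_bce_fully_masked_resolution_drops_out():
    pred = _maps([np.full((1, 10), 0.5), np.full((1, 5), 0.9),
                  np.full((1, 3), 0.5)])
    tgt = [np.full((1, 10), -1, np.int8), np.ones((1, 5), np.int8),
           np.full((1, 3), -1, np.int8)]
    assert masked_bce(pred, tgt) == pytest.approx(-np.log(0.9), abs=1e-9)


def test_bce_all_masked_raises():
    pred = _maps([np.full((1, 4), 0.5)] * 3)
    tgt = [np.full((1, 4), -1, np.int8)] * 3
    with pytest.raises(RecordError):
        masked_bce(pred, tgt)


def test_bce_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    pred = [rng.uniform(0.05, 0.95, (2, 30)) for _ in range(3)]
    tgt = [rng.integers(-1, 2, (2, 30)).astype(np.int8) for _ in range(3)]
    _, grads = masked_bce_with_grad(pred, tgt)
    eps = 1e-6
    for r in range(3):
        for idx in [(0, 3), (1, 17), (0, 29)]:
            pp = [p.copy() for p in pred]
            pp[r][idx] += eps
            lp = masked_bce(pp, tgt)
            pp[r][idx] -= 2 * eps
            lm = masked_bce(pp, tgt)
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(grads[r][idx]), rel=1e-4, abs=1e-8)
    # gradient is exactly zero at ignored points
    for g, t in zip(grads, tgt):
        assert np.all(np.asarray(g)[t == -1] == 0.0)


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 2**32 - 1))
def test_bce_invariant_to_values_at_ignored_points(seed):
    """Property: the loss never depends on predictions where target = -1."""
    rng = np.random.default_rng(seed)
    tgt = [rng.integers(-1, 2, (1, n)).astype(np.int8) for n in (40, 20, 10)]
    if all(np.all(t == -1) for t in tgt):
        tgt[0][0, 20] = 1
    pred = [rng.uniform(0.0, 1.0, t.shape) for t in tgt]
    base = masked_bce(pred, tgt)
    pred2 = [p.copy() for p in pred]
    for p, t in zip(pred2, tgt):
        p[t == -1] = rng.uniform(0.0, 1.0, int(np.sum(t == -1)))
    assert masked_bce(pred2, tgt) == base


def test_bce_shape_mismatch_raises():
    with pytest.raises(RecordError):
        masked_bce(_maps([np.zeros((1, 10))] * 3),
                   [np.zeros((1, 9), np.int8)] * 3)


def test_slice_segments_counts():
    rec = simulate_segment(SimConfig(duration_s=70.0, bpm=60.0, snr_db=None))
    assert len(slice_segments(rec, 60.0)) == 1
    assert len(slice_segments(rec, 35.0)) == 2
    segs = slice_segments(rec, 10.0)
    assert len(segs) == 7
    for sig, ann in segs:
        assert sig.shape[0] == 2500
        assert np.all((ann >= 0) & (ann < 2500))
    total = sum(len(ann) for _, ann in segs)
    assert total == len(rec.annotations)


def test_slice_segments_local_annotation_offsets():
    rec = simulate_segment(SimConfig(duration_s=20.0, bpm=60.0, snr_db=None))
    segs = slice_segments(rec, 10.0)
    glob = rec.annotation_samples()
    recon = np.concatenate(
        [ann + i * 2500 for i, (_, ann) in enumerate(segs)]
    )
    assert np.array_equal(recon, glob)


def _tiny_dataset(n, seed, dur=20.0):
    rng = np.random.default_rng(seed)
    return [
        simulate_segment(SimConfig(duration_s=dur, bpm=float(rng.uniform(60, 120)),
                                   snr_db=8.0, seed=int(rng.integers(1 << 31))))
        for _ in range(n)
    ]


def test_fit_zero_epochs_keeps_weights():
    model = QRSNet(TINY_CFG, seed=0)
    before = model.state_dict()
    res = fit(model, _tiny_dataset(2, 0), _tiny_dataset(1, 1),
              Hyper(epochs=0, batch=2, seg_s=20.0))
    assert res.best_epoch == -1 and res.history == []
    after = model.state_dict()
    for k in before:
        assert np.array_equal(before[k], after[k])


def test_fit_deterministic_given_seed():
    h = Hyper(epochs=1, batch=2, seg_s=20.0, seed=3)
    outs = []
    for _ in range(2):
        model = QRSNet(TINY_CFG, seed=0)
        res = fit(model, _tiny_dataset(3, 0), _tiny_dataset(1, 1), h)
        outs.append((res.history, model.state_dict()))
    assert outs[0][0] == outs[1][0]
    for k in outs[0][1]:
        assert np.array_equal(outs[0][1][k], outs[1][1][k])


def test_fit_reduces_validation_loss():
    model = QRSNet(TINY_CFG, seed=0)
    train = _tiny_dataset(6, 10)
    val = _tiny_dataset(2, 11)
    res = fit(model, train, val, Hyper(epochs=3, batch=3, seg_s=20.0, seed=4))
    first = res.history[0]["val_loss"]
    best = min(e["val_loss"] for e in res.history)
    assert best < first
    assert res.best_epoch == min(
        i for i, e in enumerate(res.history)
        if e["val_loss"] == best
    )
    # the model carries the best epoch's weights
    from qrspeak.train import _prep_segments

    segs = _prep_segments(val, 20.0)
    assert evaluate_loss(model, segs, 4) == pytest.approx(best, abs=1e-6)


def test_fit_requires_records():
    model = QRSNet(TINY_CFG, seed=0)
    with pytest.raises(RecordError):
        fit(model, [], _tiny_dataset(1, 0), Hyper(epochs=1))
    with pytest.raises(RecordError):
        fit(model, _tiny_dataset(1, 0), _tiny_dataset(1, 1),
            Hyper(epochs=1, seg_s=60.0))  # records shorter than one segment


def test_ar_ds2_split_is_patientwise():
    from qrspeak.train import AR_DS2_TRAIN_RECORDS, AR_DS2_VAL_RECORDS

    assert len(AR_DS2_TRAIN_RECORDS) == 15
    assert len(AR_DS2_VAL_RECORDS) == 7
    assert not set(AR_DS2_TRAIN_RECORDS) & set(AR_DS2_VAL_RECORDS)
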
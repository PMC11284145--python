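"""Training: masked binary cross-entropy, segmentation, augmentation, fit.

The loss is binary cross-entropy over the three heat maps, averaged over
non-ignored points per resolution and then averaged (unweighted) over
the resolutions; a fully masked resolution drops out of the mean.

The optimizer settings follow the published protocol: Adam, learning
rate 1e-3, batch size 32, weight decay 1e-8, 5 epochs, 60-s training
segments, and the checkpoint with the lowest validation loss wins
(ties go to the earlier epoch).

Augmentation per training segment (rates are package defaults, the
source protocol names the families but not the rates; all configurable):

* with probability 0.3, mix one of baseline wander / muscle artifact /
  electrode motion into each lead at an SNR drawn uniformly from
  [4, 12] dB;
* each channel's sign is flipped with probability 0.5 and the channels
  are swapped with probability 0.5;
* 10% of each epoch's batches are purely simulated high-heart-rate
  segments (200-280 BPM, 3-5 mV, 50-100 ms QRS, 4-12 dB white noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import QRSNet
from .preprocess import preprocess_record
from .records import ECGRecord, RecordError
from .simulate import (
    SimConfig,
    augment_channels,
    gen_baseline_wander,
    gen_electrode_motion,
    gen_muscle_artifact,
    mix_at_snr,
    simulate_segment,
)
from .targets import TargetSet, make_targets

_CLIP = 1e-7

#: Patient-wise train/validation split of the MIT-BIH Arrhythmia Database
#: second division (DS2) used for fine-tuning experiments.  Requires the
#: PhysioNet data downloaded locally; nothing in the package ships it.
AR_DS2_TRAIN_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219",
)
AR_DS2_VAL_RECORDS = ("221", "222", "228", "231", "232", "233", "234")


@dataclass
class Hyper:
    lr: float = 1e-3
    epochs: int = 5
    batch: int = 32
    weight_decay: float = 1e-8
    seed: int = 0
    seg_s: float = 60.0
    noise_prob: float = 0.3
    flip_prob: float = 0.5
    swap_prob: float = 0.5
    sim_batch_frac: float = 0.1
    snr_range_db: tuple[float, float] = (4.0, 12.0)
    sim_bpm_range: tuple[float, float] = (200.0, 280.0)


@dataclass
class FitResult:
    state_dict: dict
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def masked_bce(pred, target) -> float:
    """Mean masked BCE over the three heat maps (see module docstring)."""
    loss, _ = masked_bce_with_grad(pred, target, want_grad=False)
    return loss


def masked_bce_with_grad(pred, target, want_grad: bool = True):
    """Return ``(loss, grads)`` where grads match the map shapes.

    ``pred`` is a sequence of three arrays (heat maps, values in [0, 1]);
    ``target`` a sequence of three integer label arrays over {1, 0, -1}
    of identical shapes.  Gradients are zero at ignored points.
    """
    terms = []
    grads = []
    for p, y in zip(pred, target):
        p = np.asarray(p, dtype=np.float64)
        y = np.asarray(y)
        if p.shape != y.shape:
            raise RecordError(f"shape mismatch: pred {p.shape} vs target {y.shape}")
        mask = y != -1
        n_valid = int(mask.sum())
        if n_valid == 0:
            grads.append(np.zeros(p.shape, dtype=nn.DTYPE))
            continue
        pc = np.clip(p, _CLIP, 1.0 - _CLIP)
        yv = (y == 1).astype(np.float64)
        bce = -(yv * np.log(pc) + (1.0 - yv) * np.log1p(-pc))
        terms.append(float(bce[mask].mean()))
        if want_grad:
            g = np.zeros(p.shape, dtype=np.float64)
            g[mask] = ((pc[mask] - yv[mask]) / (pc[mask] * (1.0 - pc[mask]))
                       / n_valid)
            grads.append(g)
        else:
            grads.append(None)
    if not terms:
        raise RecordError("all resolutions fully masked: degenerate batch")
    loss = float(np.mean(terms))
    if want_grad:
        n_res = len(terms)
        grads = [
            (g / n_res).astype(nn.DTYPE) if g is not None else None
            for g in grads
        ]
    return loss, grads


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def slice_segments(rec: ECGRecord, seg_s: float = 60.0):
    """Cut a record into consecutive non-overlapping ``seg_s`` windows.

    The final partial window is dropped.  Annotations are re-indexed to
    window-local sample offsets.  Returns ``[(signal, ann_samples), ...]``.
    """
    seg_len = int(round(seg_s * rec.fs))
    if seg_len <= 0:
        raise RecordError("segment length must be positive")
    ann = rec.annotation_samples()
    out = []
    for start in range(0, rec.n_samples - seg_len + 1, seg_len):
        a = ann[(ann >= start) & (ann < start + seg_len)] - start
        out.append((rec.signal[start : start + seg_len], a))
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _prep_segments(records, seg_s):
    """Preprocess records and slice into (2, L) float32 segments + targets."""
    segs = []
    for rec in records:
        pre = preprocess_record(rec)
        for sig, ann in slice_segments(pre, seg_s):
            x = np.ascontiguousarray(sig.T, dtype=nn.DTYPE)
            tgt = make_targets(ann, x.shape[1], pre.fs)
            segs.append((x, tgt))
    return segs


def _stack_targets(tgts: list[TargetSet]) -> list[np.ndarray]:
    return [np.stack([t.labels[r] for t in tgts]) for r in range(3)]


def _simulated_batch(n, seg_s, hyper: Hyper, rng):
    segs = []
    for _ in range(n):
        cfg = SimConfig(
            duration_s=seg_s,
            bpm=rng.uniform(*hyper.sim_bpm_range),
            qrs_amp_mv=rng.uniform(3.0, 5.0),
            qrs_dur_ms=rng.uniform(50.0, 100.0),
            snr_db=rng.uniform(*hyper.snr_range_db),
            seed=int(rng.integers(1 << 31)),
        )
        rec = preprocess_record(simulate_segment(cfg))
        x = np.ascontiguousarray(rec.signal.T, dtype=nn.DTYPE)
        segs.append((x, make_targets(rec.annotation_samples(), x.shape[1], rec.fs)))
    return segs


def _augment(x: np.ndarray, hyper: Hyper, rng) -> np.ndarray:
    sig = x.T.astype(np.float64)  # (L, 2)
    if rng.random() < hyper.noise_prob:
        kind = rng.integers(3)
        snr = rng.uniform(*hyper.snr_range_db)
        for j in range(2):
            seed = int(rng.integers(1 << 31))
            n = sig.shape[0]
            if kind == 0:
                noise = gen_baseline_wander(n, 250.0, 1.0, seed)
            elif kind == 1:
                noise = gen_muscle_artifact(n, seed)
            else:
                noise = gen_electrode_motion(n, 250.0, seed)
            sig[:, j] = mix_at_snr(sig[:, j], noise, snr)
    flips = (rng.random() < hyper.flip_prob, rng.random() < hyper.flip_prob)
    swap = rng.random() < hyper.swap_prob
    sig = augment_channels(sig, flips, swap)
    return np.ascontiguousarray(sig.T, dtype=nn.DTYPE)


def evaluate_loss(model: QRSNet, segs, batch: int = 32) -> float:
    """Mean masked BCE of a model over preprocessed segments."""
    losses, weights = [], []
    for i in range(0, len(segs), batch):
        chunk = segs[i : i + batch]
        x = np.stack([s[0] for s in chunk])
        maps = model.forward(x)
        loss, _ = masked_bce_with_grad(
            maps, _stack_targets([s[1] for s in chunk]), want_grad=False
        )
        losses.append(loss)
        weights.append(len(chunk))
    return float(np.average(losses, weights=weights))


def fit(
    model: QRSNet,
    train_records,
    val_records,
    hyper: Hyper = Hyper(),
    log=None,
) -> FitResult:
    """Train a model; return the best-on-validation checkpoint.

    Reproducible given ``hyper.seed`` (all shuffling, augmentation and
    simulation randomness derives from it).  ``epochs=0`` returns the
    initial weights unchanged.  Raises on NaN loss.
    """
    if not train_records or not val_records:
        raise RecordError("need at least one training and one validation record")
    rng = np.random.default_rng(hyper.seed)
    train_segs = _prep_segments(train_records, hyper.seg_s)
    val_segs = _prep_segments(val_records, hyper.seg_s)
    if not train_segs or not val_segs:
        raise RecordError("records shorter than one segment")

    opt = nn.Adam(model.parameters(), lr=hyper.lr,
                  weight_decay=hyper.weight_decay)
    result = FitResult(state_dict=model.state_dict())
    best_val = np.inf

    for epoch in range(hyper.epochs):
        order = rng.permutation(len(train_segs))
        n_batches = max(1, len(order) // hyper.batch)
        train_losses = []
        for b in range(n_batches):
            if rng.random() < hyper.sim_batch_frac:
                chunk = _simulated_batch(hyper.batch, hyper.seg_s, hyper, rng)
            else:
                idx = order[b * hyper.batch : (b + 1) * hyper.batch]
                chunk = [train_segs[i] for i in idx]
            x = np.stack([_augment(s[0], hyper, rng) for s in chunk])
            maps = model.forward(x)
            loss, grads = masked_bce_with_grad(
                maps, _stack_targets([s[1] for s in chunk])
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch} batch {b}")
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            train_losses.append(loss)
        val_loss = evaluate_loss(model, val_segs, hyper.batch)
        entry = dict(epoch=epoch, train_loss=float(np.mean(train_losses)),
                     val_loss=val_loss)
        result.history.append(entry)
        if log:
            log(entry)
        if val_loss < best_val:
            best_val = val_loss
            result.state_dict = model.state_dict()
            result.best_epoch = epoch
    model.load_state_dict(result.state_dict)
    return result
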
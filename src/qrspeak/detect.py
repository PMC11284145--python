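"""Turning heat maps into QRS locations.

A sample is a candidate when its heat-map response exceeds the threshold
(0.5 by default) and is a local maximum; runs of equal values that form
a plateau emit their (left-)center sample once.  Greedy non-maximum
suppression then keeps the highest-probability candidate and discards
every other candidate within 200 ms of it, repeating until no candidates
remain.  No search-back or adaptive thresholding is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MIN_INPUT_LEN, QRSNet
from .preprocess import CANONICAL_FS, preprocess_record
from .records import ECGRecord, RecordError

DEFAULT_THRESHOLD = 0.5
DEFAULT_NMS_WINDOW_MS = 200.0


@dataclass(frozen=True)
class Candidate:
    sample: int
    prob: float


@dataclass
class DetectionResult:
    """Predicted QRS locations, ascending, with probabilities."""

    samples: np.ndarray
    probs: np.ndarray
    fs: float

    def __len__(self):
        return len(self.samples)

    def times_s(self) -> np.ndarray:
        return self.samples / self.fs


def find_candidates(
    heat: np.ndarray, fs: float, thr: float = DEFAULT_THRESHOLD
) -> list[Candidate]:
    """Local maxima of a heat map above the threshold.

    A plateau (run of equal values) that is a local maximum contributes a
    single candidate at its center sample (the left-center on runs of
    even length).  Border samples may qualify: the out-of-range neighbour
    counts as minus infinity.
    """
    h = np.asarray(heat, dtype=np.float64)
    if h.ndim != 1:
        raise RecordError("heat map must be 1-D")
    n = h.size
    if n == 0:
        return []
    out: list[Candidate] = []
    # run-length walk over equal-value plateaus
    start = 0
    while start < n:
        end = start
        while end + 1 < n and h[end + 1] == h[start]:
            end += 1
        v = h[start]
        left_ok = start == 0 or h[start - 1] < v
        right_ok = end == n - 1 or h[end + 1] < v
        if v > thr and left_ok and right_ok:
            out.append(Candidate(sample=(start + end) // 2, prob=float(v)))
        start = end + 1
    return out


def nms(
    cands: list[Candidate], fs: float, window_ms: float = DEFAULT_NMS_WINDOW_MS
) -> DetectionResult:
    """Greedy non-maximum suppression over a temporal window.

    Candidates are processed in descending probability (ties go to the
    earlier sample); accepting a candidate suppresses every remaining
    candidate within ``window_ms`` (closed interval) of it.
    """
    order = sorted(cands, key=lambda c: (-c.prob, c.sample))
    window_s = window_ms / 1000.0
    kept: list[Candidate] = []
    alive = [True] * len(order)
    for i, c in enumerate(order):
        if not alive[i]:
            continue
        kept.append(c)
        for j in range(i + 1, len(order)):
            if alive[j] and abs(order[j].sample - c.sample) / fs <= window_s:
                alive[j] = False
    kept.sort(key=lambda c: c.sample)
    return DetectionResult(
        samples=np.array([c.sample for c in kept], dtype=np.int64),
        probs=np.array([c.prob for c in kept], dtype=np.float64),
        fs=fs,
    )


def detect_record(
    model: QRSNet,
    rec: ECGRecord,
    thr: float = DEFAULT_THRESHOLD,
    window_ms: float = DEFAULT_NMS_WINDOW_MS,
    map_index: int = 0,
    preprocess: bool = True,
) -> DetectionResult:
    """Detect QRS complexes in a record.

    The record is brought to canonical form, the model is run, candidates
    are extracted from the full-resolution heat map (``map_index=0``;
    other maps are exposed for experimentation) and suppressed; the
    detections are mapped back to the record's native sample coordinates.
    """
    pre = preprocess_record(rec) if preprocess else rec
    if pre.n_samples < MIN_INPUT_LEN:
        raise RecordError("record shorter than the minimum model input")
    x = np.ascontiguousarray(pre.signal.T)[None, :, :]
    heat = model.forward(x)[map_index][0]
    map_fs = pre.fs / (1, 2, 4)[map_index]
    det = nms(find_candidates(heat, map_fs, thr), map_fs, window_ms)
    if rec.fs != map_fs:
        native = np.floor(det.samples * (rec.fs / map_fs) + 0.5).astype(np.int64)
        native = np.minimum(native, rec.n_samples - 1)
        det = DetectionResult(samples=native, probs=det.probs, fs=rec.fs)
    return det
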
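"""Scoring detections against beat annotations.

A detection is a true positive when it lies within the tolerance window
(default 0.15 s, strict) of an annotated beat; matching is one-to-one:
detections are processed in ascending time and each takes the nearest
still-unmatched annotation (equidistant ties go to the earlier
annotation).  Unmatched detections are false positives, unmatched
annotations false negatives.

Summary statistics:

    Sen = TP / (TP + FN) * 100
    Pre = TP / (TP + FP) * 100
    Err = (FP + FN) / (TP + FN + FP) * 100
    Fnr = FN / (TP + FN) * 100          (per AAMI beat type)

plus the margin: mean +/- sample standard deviation of the absolute
time offset (ms) between each true positive and its matched beat.
Offsets are computed in seconds at the record's native rate, so records
at any sampling frequency score correctly.  Err can exceed 100 when
false positives outnumber the beats - the formula permits it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BeatAnnotation, RecordError

DEFAULT_TOLERANCE_S = 0.15


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    sen: float | None
    pre: float | None
    err: float | None
    fnr_by_type: dict[str, float] = field(default_factory=dict)
    margin_mean_ms: float | None = None
    margin_sd_ms: float | None = None
    tolerance_s: float = DEFAULT_TOLERANCE_S

    def rounded(self) -> dict:
        """Reporting view: percentages rounded to 2 decimals."""
        r2 = lambda v: None if v is None else round(v, 2)
        return dict(
            tp=self.tp, fp=self.fp, fn=self.fn,
            sen=r2(self.sen), pre=r2(self.pre), err=r2(self.err),
            fnr_by_type={k: r2(v) for k, v in self.fnr_by_type.items()},
            margin_mean_ms=r2(self.margin_mean_ms),
            margin_sd_ms=r2(self.margin_sd_ms),
            tolerance_s=self.tolerance_s,
        )


def match(
    detections,
    annotations,
    fs: float,
    tol_s: float = DEFAULT_TOLERANCE_S,
):
    """One-to-one matching of detections to annotated beats.

    Parameters
    ----------
    detections:
        Ascending detection sample indices.
    annotations:
        Ascending annotation sample indices, or ``BeatAnnotation`` list.
    fs:
        Sampling rate both index lists refer to.

    Returns
    -------
    (pairs, fp_list, fn_list):
        ``pairs`` is a list of ``(det_index, ann_index)``; ``fp_list``
        the unmatched detection indices; ``fn_list`` the unmatched
        annotation indices (all indices into the input lists).
    """
    det = np.asarray(
        [d.sample if hasattr(d, "sample") else d for d in detections],
        dtype=np.int64,
    )
    ann = np.asarray(
        [a.sample if isinstance(a, BeatAnnotation) else a for a in annotations],
        dtype=np.int64,
    )
    if np.any(np.diff(det) < 0) or np.any(np.diff(ann) < 0):
        raise RecordError("detections and annotations must be sorted ascending")
    unmatched = np.ones(ann.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    fp: list[int] = []
    for i, d in enumerate(det):
        cand = np.flatnonzero(unmatched)
        if cand.size == 0:
            fp.append(i)
            continue
        dist = np.abs(ann[cand] - d)
        j = cand[int(np.argmin(dist))]  # argmin returns the first (earlier) tie
        if abs(ann[j] - d) / fs < tol_s:
            unmatched[j] = False
            pairs.append((i, int(j)))
        else:
            fp.append(i)
    fn = [int(j) for j in np.flatnonzero(unmatched)]
    return pairs, fp, fn


def metrics(tp: int, fp: int, fn: int):
    """(Sen, Pre, Err) percentages; ``None`` for undefined denominators."""
    sen = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    pre = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    err = 100.0 * (fp + fn) / (tp + fn + fp) if tp + fn + fp > 0 else None
    return sen, pre, err


def fnr_by_type(fn_list, pairs, annotations) -> dict[str, float]:
    """False-negative rate per AAMI type; absent types are omitted.

    A true positive inherits the type of its matched annotation.
    """
    tp_count: dict[str, int] = {}
    fn_count: dict[str, int] = {}
    for _, j in pairs:
        t = annotations[j].aami_type
        tp_count[t] = tp_count.get(t, 0) + 1
    for j in fn_list:
        t = annotations[j].aami_type
        fn_count[t] = fn_count.get(t, 0) + 1
    out = {}
    for t in sorted(set(tp_count) | set(fn_count)):
        n = tp_count.get(t, 0) + fn_count.get(t, 0)
        out[t] = 100.0 * fn_count.get(t, 0) / n
    return out


def margin_stats(pairs, detections, annotations, fs: float):
    """Mean and sample sd (ms) of |offset| over true-positive pairs.

    A single pair (or none) reports sd 0; no pairs reports ``(None, None)``.
    """
    det = np.asarray(
        [d.sample if hasattr(d, "sample") else d for d in detections],
        dtype=np.int64,
    )
    ann = np.asarray(
        [a.sample if isinstance(a, BeatAnnotation) else a for a in annotations],
        dtype=np.int64,
    )
    offs = np.array(
        [abs(det[i] - ann[j]) / fs * 1000.0 for i, j in pairs], dtype=np.float64
    )
    if offs.size == 0:
        return None, None
    sd = float(np.std(offs, ddof=1)) if offs.size > 1 else 0.0
    return float(np.mean(offs)), sd


def evaluate(
    detections,
    annotations,
    fs: float,
    tol_s: float = DEFAULT_TOLERANCE_S,
) -> EvalReport:
    """Full scoring of one record (or a concatenated set)."""
    ann_list = list(annotations)
    typed = ann_list and isinstance(ann_list[0], BeatAnnotation)
    pairs, fp, fn = match(detections, ann_list, fs, tol_s)
    sen, pre, err = metrics(len(pairs), len(fp), len(fn))
    mean_ms, sd_ms = margin_stats(pairs, detections, ann_list, fs)
    return EvalReport(
        tp=len(pairs), fp=len(fp), fn=len(fn),
        sen=sen, pre=pre, err=err,
        fnr_by_type=fnr_by_type(fn, pairs, ann_list) if typed else {},
        margin_mean_ms=mean_ms, margin_sd_ms=sd_ms,
        tolerance_s=tol_s,
    )


def evaluate_many(items, tol_s: float = DEFAULT_TOLERANCE_S) -> EvalReport:
    """Pooled scoring over several records.

    ``items`` is an iterable of ``(detections, annotations, fs)``; counts,
    per-type rates and margins are accumulated over all records before
    the summary statistics are computed, which is exact (unlike averaging
    per-record reports).
    """
    tp = fp_n = 0
    offsets: list[float] = []
    tp_count: dict[str, int] = {}
    fn_count: dict[str, int] = {}
    fn_n = 0
    for detections, annotations, fs in items:
        ann_list = list(annotations)
        typed = ann_list and isinstance(ann_list[0], BeatAnnotation)
        pairs, fp, fn = match(detections, ann_list, fs, tol_s)
        tp += len(pairs)
        fp_n += len(fp)
        fn_n += len(fn)
        det = np.asarray(
            [d.sample if hasattr(d, "sample") else d for d in detections],
            dtype=np.int64,
        )
        for i, j in pairs:
            a = ann_list[j]
            s = a.sample if isinstance(a, BeatAnnotation) else a
            offsets.append(abs(int(det[i]) - int(s)) / fs * 1000.0)
            if typed:
                tp_count[a.aami_type] = tp_count.get(a.aami_type, 0) + 1
        if typed:
            for j in fn:
                t = ann_list[j].aami_type
                fn_count[t] = fn_count.get(t, 0) + 1
    sen, pre, err = metrics(tp, fp_n, fn_n)
    fnr = {}
    for t in sorted(set(tp_count) | set(fn_count)):
        n = tp_count.get(t, 0) + fn_count.get(t, 0)
        fnr[t] = 100.0 * fn_count.get(t, 0) / n
    offs = np.asarray(offsets)
    mean_ms = float(offs.mean()) if offs.size else None
    sd_ms = (float(np.std(offs, ddof=1)) if offs.size > 1
             else (0.0 if offs.size else None))
    return EvalReport(
        tp=tp, fp=fp_n, fn=fn_n, sen=sen, pre=pre, err=err,
        fnr_by_type=fnr, margin_mean_ms=mean_ms, margin_sd_ms=sd_ms,
        tolerance_s=tol_s,
    )
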
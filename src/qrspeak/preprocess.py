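"""Canonical signal conditioning for the detector.

Every record is brought to the model's canonical representation before
inference or training: resampled to 250 Hz, band-pass filtered to
0.5-35 Hz with a zero-phase Butterworth filter, z-scored per lead, and
expanded to two channels (a single lead is duplicated).

Zero-phase (forward-backward) filtering is used so that the group delay
of the filter does not shift the annotated QRS positions.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .records import BeatAnnotation, ECGRecord, RecordError

CANONICAL_FS = 250.0
#: Butterworth section order; the effective magnitude response is squared
#: by the forward-backward application.
FILTER_ORDER = 3


def resample_record(rec: ECGRecord, target_fs: float = CANONICAL_FS) -> ECGRecord:
    """Resample a record to ``target_fs`` (polyphase method).

    Annotation sample indices are rescaled by ``target_fs / rec.fs`` and
    rounded to the nearest sample (ties round half away from zero).  Beat
    count and ordering are preserved.
    """
    if rec.fs == target_fs:
        return rec.with_(signal=rec.signal.copy())
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(rec.signal, up, down, axis=0)
    n_out = out.shape[0]
    scale = target_fs / rec.fs
    anns = []
    prev = -1
    for a in rec.annotations:
        s = int(np.floor(a.sample * scale + 0.5))  # half away from zero (s >= 0)
        s = min(max(s, prev + 1), n_out - 1)  # keep strictly increasing, in range
        anns.append(BeatAnnotation(s, a.aami_type, a.raw_symbol))
        prev = s
    return rec.with_(signal=out, fs=float(target_fs), annotations=anns)


def _design_bandpass(fs: float, low: float, high: float):
    if not 0 < low < high < fs / 2:
        raise RecordError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"({low}, {high}) at fs={fs}"
        )
    return sps.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs)


def bandpass(
    signal: np.ndarray, fs: float, low: float = 0.5, high: float = 35.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per lead.

    The default 0.5-35 Hz band removes baseline drift and attenuates
    mains interference and high-frequency muscle noise while keeping the
    QRS energy (roughly 5-25 Hz) intact.
    """
    b, a = _design_bandpass(fs, low, high)
    x = np.asarray(signal, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    # filtfilt needs more samples than its edge padding (3 * taps)
    if x.shape[0] <= 3 * max(len(a), len(b)):
        raise RecordError("signal too short to filter")
    y = sps.filtfilt(b, a, x, axis=0)
    return y[:, 0] if squeeze else y


def zscore_leads(signal: np.ndarray) -> np.ndarray:
    """Z-score each lead to zero mean, unit variance.

    A lead with zero variance (flat line) maps to all-zeros instead of
    dividing by zero, so degenerate segments survive batch pipelines.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if x.shape[0] < 2:
        raise RecordError("need at least 2 samples per lead to z-score")
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    out = np.zeros_like(x)
    ok = sd[0] > 0
    out[:, ok] = (x[:, ok] - mean[:, ok]) / sd[:, ok]
    return out


def ensure_dual_channel(signal: np.ndarray) -> np.ndarray:
    """Return an ``[n, 2]`` signal; a single lead is duplicated."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.size == 0:
        raise RecordError("empty signal")
    if x.shape[1] == 1:
        return np.repeat(x, 2, axis=1)
    if x.shape[1] == 2:
        return x.copy()
    raise RecordError(f"expected 1 or 2 leads, got {x.shape[1]}")


def preprocess_record(rec: ECGRecord, target_fs: float = CANONICAL_FS) -> ECGRecord:
    """Full canonical pipeline: resample, band-pass, z-score, dual channel."""
    rec = resample_record(rec, target_fs)
    x = bandpass(rec.signal, rec.fs)
    x = zscore_leads(x)
    x = ensure_dual_channel(x)
    names = rec.lead_names if len(rec.lead_names) == 2 else [
        rec.lead_names[0], rec.lead_names[0] + "_dup"
    ]
    return rec.with_(signal=x, lead_names=names)
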
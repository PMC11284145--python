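"""Reading and writing WFDB records, beat annotations, and detections.

Implements the subset of the WFDB format family needed here:

* headers (``.hea``) with one signal file per record,
* signal files (``.dat``) in format 16 (read/write) and format 212 (read),
* MIT annotation files (``.atr`` and friends) read/write,
* CSV serialization of detections and evaluation reports.

Physical units follow the WFDB convention ``physical = (adc - baseline) / gain``
with gain in ADC units per millivolt.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .records import (
    BEAT_SYMBOLS,
    BeatAnnotation,
    ECGRecord,
    RecordError,
    map_symbol_to_aami,
)

__all__ = [
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "write_detections",
    "read_detections",
    "map_symbol_to_aami",
]

# MIT annotation code <-> symbol table (label store values).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# ---------------------------------------------------------------------------
# annotation files (MIT format)
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file.

    Returns a list of ``(sample, symbol)`` pairs for every stored
    annotation, beats and non-beats alike, in file order.
    """
    data = Path(path).read_bytes()
    words = np.frombuffer(data, dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(words)
    while i < n:
        word = int(words[i])
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # EOF
            break
        if code == _SKIP:
            if i + 2 >= n:
                raise RecordError("truncated SKIP in annotation file")
            # 4-byte interval, high 16 bits first (PDP-11 order)
            interval = (int(words[i + 1]) << 16) | int(words[i + 2])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 3
            continue
        if code == _AUX:
            i += 1 + (delta + 1) // 2
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        t += delta
        out.append((t, _CODE_TO_SYMBOL.get(code, "Q")))
        i += 1
    return out


def write_annotations(path, annotations: list[tuple[int, str]]) -> None:
    """Write ``(sample, symbol)`` pairs as an MIT-format annotation file.

    Samples must be sorted ascending.
    """
    samples = [s for s, _ in annotations]
    if any(b < a for a, b in zip(samples, samples[1:])):
        raise RecordError("annotations must be sorted ascending by sample")
    words: list[int] = []
    prev = 0
    for sample, symbol in annotations:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise RecordError(f"unknown annotation symbol: {symbol!r}")
        delta = int(sample) - prev
        if delta < 0:
            raise RecordError("negative annotation interval")
        if delta > 1023:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        prev = int(sample)
    words.append(0)  # EOF
    Path(path).write_bytes(np.asarray(words, dtype="<u2").tobytes())


# ---------------------------------------------------------------------------
# signal files + headers
# ---------------------------------------------------------------------------

def _parse_header(path: Path):
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise RecordError(f"empty header: {path}")
    head = lines[0].split()
    if len(head) < 4:
        raise RecordError(f"malformed header line: {lines[0]!r}")
    record_id = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fname = f[0]
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, None, "mV"
        if len(f) > 2:
            g = f[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(f[8:]) if len(f) > 8 else ""
        sigs.append(dict(fname=fname, fmt=fmt, gain=gain, baseline=baseline,
                         units=units, desc=desc))
    return record_id, nsig, fs, n_samples, sigs


def _read_dat(path: Path, fmt: str, nsig: int, n_samples: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == "16":
        adc = np.frombuffer(raw, dtype="<i2")
        adc = adc[: nsig * n_samples].reshape(-1, nsig)
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        n_pairs = len(b) // 3
        b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int64)
        s1 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        s2 = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        flat = np.empty(2 * n_pairs, dtype=np.int64)
        flat[0::2], flat[1::2] = s1, s2
        flat[flat > 2047] -= 4096  # 12-bit two's complement
        adc = flat[: nsig * n_samples].reshape(-1, nsig)
    else:
        raise RecordError(f"unsupported WFDB signal format: {fmt}")
    if adc.shape[0] < n_samples:
        raise RecordError(f"signal file shorter than header claims: {path}")
    return adc


def read_record(path, max_leads: int = 2) -> ECGRecord:
    """Read a WFDB record (header, signal, optional ``.atr`` annotations).

    Parameters
    ----------
    path:
        Path to the record, with or without the ``.hea`` extension.
    max_leads:
        Keep at most this many leads; records with more are truncated to
        the first ``max_leads`` with a warning (the detector has exactly
        two input channels).

    Returns
    -------
    ECGRecord
        Signal in millivolts; beat annotations only (non-beat annotations
        such as rhythm changes or noise markers are dropped).
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    record_id, nsig, fs, n_samples, sigs = _parse_header(hea)
    if n_samples <= 0:
        raise RecordError(f"zero-length signal in {hea}")
    fnames = {s["fname"] for s in sigs}
    if len(fnames) != 1:
        raise RecordError("multi-file records are not supported")
    adc = _read_dat(hea.parent / sigs[0]["fname"], sigs[0]["fmt"], nsig, n_samples)
    gains = np.array([s["gain"] for s in sigs])
    baselines = np.array([s["baseline"] for s in sigs])
    physical = (adc[:n_samples].astype(np.float64) - baselines) / gains
    lead_names = [s["desc"] or f"lead{i}" for i, s in enumerate(sigs)]
    if nsig > max_leads:
        warnings.warn(
            f"record {record_id} has {nsig} leads; keeping the first {max_leads}"
        )
        physical = physical[:, :max_leads]
        lead_names = lead_names[:max_leads]

    annotations: list[BeatAnnotation] = []
    atr = hea.with_suffix(".atr")
    if atr.exists():
        for sample, symbol in read_annotations(atr):
            if symbol in BEAT_SYMBOLS and 0 <= sample < n_samples:
                annotations.append(
                    BeatAnnotation(int(sample), map_symbol_to_aami(symbol), symbol)
                )
    return ECGRecord(
        signal=physical,
        fs=fs,
        lead_names=lead_names,
        annotations=annotations,
        record_id=record_id,
    )


def write_record(rec: ECGRecord, directory, gain: float = 200.0) -> Path:
    """Write an :class:`ECGRecord` as a WFDB record (format 16).

    Writes ``<record_id>.hea``, ``<record_id>.dat`` and, when the record
    carries annotations, ``<record_id>.atr``.  Returns the header path.

    Amplitudes are quantized to ``1/gain`` mV; the default gain of 200
    ADC units/mV gives 5 microvolt resolution.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rid = rec.record_id
    adc = np.round(rec.signal * gain).astype(np.int64)
    if np.abs(adc).max(initial=0) > 32767:
        raise RecordError("signal exceeds int16 range at this gain")
    adc = adc.astype("<i2")

    lines = [f"{rid} {rec.n_leads} {_fmt_float(rec.fs)} {rec.n_samples}"]
    for j in range(rec.n_leads):
        checksum = int(np.sum(adc[:, j].astype(np.int64)) & 0xFFFF)
        if checksum >= 0x8000:
            checksum -= 0x10000
        init = int(adc[0, j])
        lines.append(
            f"{rid}.dat 16 {_fmt_float(gain)}(0)/mV 16 0 {init} {checksum} 0 "
            f"{rec.lead_names[j]}"
        )
    (directory / f"{rid}.hea").write_text("\n".join(lines) + "\n")
    (directory / f"{rid}.dat").write_bytes(adc.reshape(-1).tobytes())
    if rec.annotations:
        write_annotations(
            directory / f"{rid}.atr",
            [(a.sample, a.raw_symbol) for a in rec.annotations],
        )
    return directory / f"{rid}.hea"


def _fmt_float(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def write_detections(det, path, record_id: str | None = None) -> None:
    """Write a :class:`~qrspeak.detect.DetectionResult` as CSV.

    One row per detection: ``record_id, sample, time_s, probability``.
    An empty result produces a header-only file.
    """
    rid = record_id if record_id is not None else getattr(det, "record_id", "")
    samples = np.asarray(det.samples, dtype=np.int64)
    if samples.size and np.any(np.diff(samples) <= 0):
        raise RecordError("detections must be sorted ascending by sample")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "sample", "time_s", "probability"])
        for s, p in zip(samples, det.probs):
            w.writerow([rid, int(s), f"{s / det.fs:.6f}", f"{float(p):.6f}"])


def read_detections(path):
    """Read a detections CSV back into a ``DetectionResult``.

    The sampling rate is reconstructed from the sample/time columns; a
    header-only file yields an empty result at 250 Hz.
    """
    from .detect import DetectionResult

    samples, probs, fs = [], [], 250.0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            samples.append(int(row["sample"]))
            probs.append(float(row["probability"]))
            t = float(row["time_s"])
            if t > 0:
                fs = int(row["sample"]) / t
    return DetectionResult(
        samples=np.asarray(samples, dtype=np.int64),
        probs=np.asarray(probs, dtype=np.float64),
        fs=fs,
    )


def write_detections_wfdb(det, path) -> None:
    """Write detections as a WFDB annotation file with symbol ``N``."""
    write_annotations(path, [(int(s), "N") for s in det.samples])
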
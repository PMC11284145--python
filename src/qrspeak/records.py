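"""Core in-memory containers for ECG records and beat annotations.

An :class:`ECGRecord` holds a multi-lead signal in physical units
(millivolts), its sampling rate, and the beat annotations that mark the
location of each QRS complex.  The detector operates on one or two leads;
records with more leads are truncated at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AAMI_TYPES = ("N", "S", "V", "F", "Q")

#: Symbol -> AAMI class mapping following the EC57 convention.
#: N: normal-like (normal, bundle branch block, escape beats);
#: S: supraventricular ectopic; V: ventricular ectopic; F: ventricular
#: fusion; Q: paced, paced fusion or unclassifiable.
_SYMBOL_TO_AAMI = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

#: All WFDB symbols that denote a beat (as opposed to rhythm changes, noise
#: markers, comments, ...).  Exotic beat symbols not in the AAMI table above
#: (e.g. "B", "n", "r", "?") deliberately fall through to class Q so that
#: scoring never crashes on unusual records.
BEAT_SYMBOLS = frozenset(
    ["N", "L", "R", "a", "V", "F", "J", "A", "S", "E", "j", "/", "Q",
     "e", "f", "n", "B", "r", "?"]
)


class RecordError(ValueError):
    """Raised for invalid record content or annotation input."""


def map_symbol_to_aami(raw_symbol: str) -> str:
    """Map a WFDB beat symbol to its AAMI class.

    Parameters
    ----------
    raw_symbol:
        A standard WFDB annotation symbol that denotes a beat.

    Returns
    -------
    str
        One of ``{"N", "S", "V", "F", "Q"}``.  Beat symbols without a
        standard AAMI assignment map to ``"Q"``.

    Raises
    ------
    RecordError
        If ``raw_symbol`` is a non-beat symbol; callers must filter
        non-beat annotations before classification.
    """
    if raw_symbol not in BEAT_SYMBOLS:
        raise RecordError(f"not a beat symbol: {raw_symbol!r}")
    return _SYMBOL_TO_AAMI.get(raw_symbol, "Q")


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotated beat: sample index, AAMI class, raw symbol."""

    sample: int
    aami_type: str
    raw_symbol: str

    def __post_init__(self):
        if self.aami_type not in AAMI_TYPES:
            raise RecordError(f"invalid AAMI type: {self.aami_type!r}")


@dataclass
class ECGRecord:
    """A multi-lead ECG signal with sampling rate and beat annotations.

    Attributes
    ----------
    signal:
        Array of shape ``(n_samples, n_leads)`` in millivolts.
    fs:
        Sampling rate in Hz, strictly positive.
    lead_names:
        One name per lead.
    annotations:
        Beat annotations with strictly increasing sample indices inside
        ``[0, n_samples)``.
    record_id:
        Short identifier used in file names and reports.
    """

    signal: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)
    annotations: list[BeatAnnotation] = field(default_factory=list)
    record_id: str = "record"

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.signal.ndim != 2:
            raise RecordError("signal must be a 2-D [n_samples, n_leads] array")
        if self.signal.shape[0] == 0:
            raise RecordError("zero-length signal")
        if not self.fs > 0:
            raise RecordError(f"sampling rate must be positive, got {self.fs}")
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.n_leads)]
        if len(self.lead_names) != self.n_leads:
            raise RecordError("lead_names length does not match signal")
        samples = [a.sample for a in self.annotations]
        if any(s2 <= s1 for s1, s2 in zip(samples, samples[1:])):
            raise RecordError("annotation samples must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.n_samples):
            raise RecordError("annotation sample outside signal span")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def annotation_samples(self) -> np.ndarray:
        """Annotation sample indices as an int array."""
        return np.array([a.sample for a in self.annotations], dtype=np.int64)

    def with_(self, **changes) -> "ECGRecord":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **changes)
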
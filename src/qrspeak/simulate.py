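"""Synthetic annotated ECG and noise generation.

The simulator produces fully annotated two-lead segments so training and
testing never require external data.  It emulates the conditions used to
augment real training data: periodic QRS pulses at a configurable heart
rate (including the 200-280 BPM high-rate regime), QRS amplitudes of
3-5 mV and durations of 50-100 ms, white noise mixed at 4-12 dB SNR, and
the three standard ECG noise processes:

* baseline wander (BW) - a low-frequency sinusoid whose frequency is
  drawn from an equal-weight mixture of three Gaussians centered at
  0.05, 0.15 and 0.25 Hz (sd = mean/3, non-positive draws rejected);
* muscle artifact (MA) - white Gaussian noise;
* electrode motion (EM) - white noise band-passed to 5-15 Hz.

The default QRS waveform is a Ricker (Gaussian second-derivative) pulse:
center-peaked with negative side lobes, which gives a sharp R-like
extremum at the annotated sample flanked by Q/S-like dips.  The waveform
is pluggable for experimentation.

The simulator makes no attempt at physiological realism beyond the QRS:
there are no P or T waves, no heart-rate variability, and the second
lead is a scaled copy of the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import BeatAnnotation, ECGRecord, RecordError
from .preprocess import _design_bandpass

BW_CENTERS_HZ = (0.05, 0.15, 0.25)
EM_BAND_HZ = (5.0, 15.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated segment.

    High-heart-rate augmentation segments use ``bpm`` in [200, 280];
    general fixtures use [40, 180].  Amplitude, duration and SNR ranges
    follow the augmentation protocol (3-5 mV, 50-100 ms, 4-12 dB).
    """

    fs: float = 250.0
    duration_s: float = 60.0
    bpm: float = 240.0
    qrs_amp_mv: float = 4.0
    qrs_dur_ms: float = 80.0
    snr_db: float | None = 6.0  # None -> noise-free
    seed: int = 0
    lead2_scale: float = 0.8

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise RecordError("fs and duration_s must be positive")
        if not 20 <= self.bpm <= 400:
            raise RecordError(f"bpm out of plausible range: {self.bpm}")
        if self.qrs_amp_mv <= 0 or self.qrs_dur_ms <= 0:
            raise RecordError("QRS amplitude and duration must be positive")
        if self.bpm * self.duration_s / 60.0 < 1:
            raise RecordError("segment too short to contain one beat")


def ricker_pulse(t: np.ndarray, duration_s: float) -> np.ndarray:
    """Ricker wavelet with unit peak, truncated to |t| <= duration/2.

    ``sigma = duration/7`` keeps essentially all of the waveform inside
    the stated total duration while leaving visible Q/S side lobes.
    """
    sigma = duration_s / 7.0
    u = (t / sigma) ** 2
    w = (1.0 - u) * np.exp(-u / 2.0)
    w[np.abs(t) > duration_s / 2.0] = 0.0
    return w


def simulate_segment(cfg: SimConfig, waveform=ricker_pulse) -> ECGRecord:
    """Generate one annotated two-lead segment.

    Beats are evenly spaced: the number of beats is
    ``round(bpm * duration / 60)`` exactly, with the k-th beat centered
    at ``(k + 1/2) * duration / n_beats`` (the effective RR interval
    equals ``60/bpm`` whenever beats fit the duration exactly).  Each
    beat is rendered with the configured amplitude and total duration,
    and annotated at the pulse center.  White noise is added per lead at
    the configured segment-level SNR.  Deterministic given the seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration_s))
    n_beats = int(np.floor(cfg.bpm * cfg.duration_s / 60.0 + 0.5))
    rr = cfg.duration_s / n_beats
    beat_times = (np.arange(n_beats) + 0.5) * rr
    t = np.arange(n) / cfg.fs

    clean = np.zeros(n)
    dur_s = cfg.qrs_dur_ms / 1000.0
    half = int(np.ceil(dur_s / 2 * cfg.fs)) + 1
    for bt in beat_times:
        c = int(round(bt * cfg.fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        clean[lo:hi] += cfg.qrs_amp_mv * waveform(t[lo:hi] - bt, dur_s)

    sig = np.stack([clean, cfg.lead2_scale * clean], axis=1)
    if cfg.snr_db is not None:
        for j in range(2):
            noise = rng.standard_normal(n)
            sig[:, j] = mix_at_snr(sig[:, j], noise, cfg.snr_db)

    anns = [
        BeatAnnotation(int(round(bt * cfg.fs)), "N", "N")
        for bt in beat_times
        if int(round(bt * cfg.fs)) < n
    ]
    return ECGRecord(
        signal=sig,
        fs=cfg.fs,
        lead_names=["sim0", "sim1"],
        annotations=anns,
        record_id=f"sim{cfg.seed}",
    )


def draw_bw_frequency(rng: np.random.Generator) -> float:
    """One baseline-wander frequency draw from the Gaussian mixture."""
    while True:
        mu = BW_CENTERS_HZ[rng.integers(len(BW_CENTERS_HZ))]
        f = rng.normal(mu, mu / 3.0)
        if f > 0:
            return float(f)


def gen_baseline_wander(
    n: int, fs: float, amp_z: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Baseline wander: one sinusoid with mixture-drawn frequency."""
    if n <= 0:
        raise RecordError("n must be positive")
    rng = np.random.default_rng(seed)
    f = draw_bw_frequency(rng)
    phase = rng.uniform(0, 2 * np.pi)
    return amp_z * np.sin(2 * np.pi * f * np.arange(n) / fs + phase)


def gen_muscle_artifact(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Muscle artifact: i.i.d. standard Gaussian noise."""
    if n <= 0:
        raise RecordError("n must be positive")
    return np.random.default_rng(seed).standard_normal(n)


def gen_electrode_motion(
    n: int, fs: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Electrode motion: white noise band-passed to 5-15 Hz."""
    white = gen_muscle_artifact(n, seed)
    b, a = _design_bandpass(fs, *EM_BAND_HZ)
    return sps.filtfilt(b, a, white)


def mix_at_snr(clean: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Return ``clean + alpha * noise`` at exactly the requested SNR.

    ``alpha`` is chosen so that ``10*log10(P_clean / P_scaled_noise)``
    equals ``snr_db``, with powers taken as mean squares over the full
    segment.
    """
    clean = np.asarray(clean, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if clean.shape != noise.shape:
        raise RecordError("clean and noise must have equal length")
    p_clean = np.mean(clean**2)
    p_noise = np.mean(noise**2)
    if p_clean == 0:
        raise RecordError("clean signal has zero power")
    if p_noise == 0:
        raise RecordError("noise has zero power")
    alpha = np.sqrt(p_clean / p_noise) * 10.0 ** (-snr_db / 20.0)
    return clean + alpha * noise


def make_synthetic_dataset(
    n_records: int,
    seed: int,
    duration_s: float = 60.0,
    bpm_range: tuple[float, float] = (50.0, 130.0),
    high_hr_frac: float = 0.1,
    high_hr_bpm_range: tuple[float, float] = (200.0, 280.0),
    snr_range_db: tuple[float, float] | None = (4.0, 12.0),
    record_prefix: str = "syn",
) -> list[ECGRecord]:
    """Generate a list of annotated synthetic records.

    A fraction ``high_hr_frac`` of the records (the last ones) uses the
    high-heart-rate regime; the rest draw BPM from ``bpm_range``.  QRS
    amplitude and duration are drawn uniformly from 3-5 mV and 50-100 ms
    per record; white-noise SNR from ``snr_range_db`` (``None`` for
    noise-free records).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_high = int(round(high_hr_frac * n_records))
    records = []
    for i in range(n_records):
        high = i >= n_records - n_high
        cfg = SimConfig(
            duration_s=duration_s,
            bpm=rng.uniform(*(high_hr_bpm_range if high else bpm_range)),
            qrs_amp_mv=rng.uniform(3.0, 5.0),
            qrs_dur_ms=rng.uniform(50.0, 100.0),
            snr_db=None if snr_range_db is None else rng.uniform(*snr_range_db),
            seed=int(rng.integers(1 << 31)),
        )
        rec = simulate_segment(cfg)
        rec.record_id = f"{record_prefix}{i:03d}"
        records.append(rec)
    return records


def augment_channels(
    signal: np.ndarray, flip_mask: tuple[bool, bool], swap: bool
) -> np.ndarray:
    """Per-channel sign flip followed by an optional channel swap.

    Applying the same ``(flip_mask, swap)`` twice is the identity when
    both flips match (each operation is an involution and flips act
    per-channel before the swap).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2:
        raise RecordError("expected an [n, 2] signal")
    out = x.copy()
    for j, flip in enumerate(flip_mask):
        if flip:
            out[:, j] = -out[:, j]
    if swap:
        out = out[:, ::-1].copy()
    return out
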
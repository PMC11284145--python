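import numpy as np
import pytest

from qrspeak.model import ModelConfig, QRSNet
from qrspeak.records import BeatAnnotation, ECGRecord
from qrspeak.simulate import SimConfig, simulate_segment

TINY_CFG = ModelConfig(channels=(4, 6, 8), fpn_channels=3)


@pytest.fixture(scope="session")
def tiny_model() -> QRSNet:
    return QRSNet(TINY_CFG, seed=0)


@pytest.fixture(scope="session")
def desk_model() -> QRSNet:
    from qrspeak.model import build_model

    return build_model("desk", seed=0)


@pytest.fixture(scope="session")
def clean_record() -> ECGRecord:
    """One noise-free simulated 30 s record at 80 BPM."""
    return simulate_segment(
        SimConfig(duration_s=30.0, bpm=80.0, snr_db=None, seed=42)
    )


@pytest.fixture(scope="session")
def noisy_record() -> ECGRecord:
    return simulate_segment(SimConfig(duration_s=30.0, bpm=80.0, snr_db=6.0, seed=43))


def make_record(n=2500, fs=250.0, ann_samples=(), leads=2, seed=0):
    rng = np.random.default_rng(seed)
    sig = rng.standard_normal((n, leads)) * 0.1
    anns = [BeatAnnotation(int(s), "N", "N") for s in ann_samples]
    return ECGRecord(signal=sig, fs=fs, annotations=anns, record_id="t")
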
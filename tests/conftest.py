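import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chronofly import synthetic_data as sd
from chronofly.schedules import LightSchedule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ld_12_12():
    return LightSchedule(12.0, 12.0)


@pytest.fixture(scope="session")
def dd():
    return LightSchedule(0.0, 24.0, regime_label="DD")


@pytest.fixture(scope="session")
def entrained_dataset(ld_12_12):
    """14 LD days, 8 flies, single evening peak at ZT 10 — the standard
    recording protocol used throughout the locomotor tests."""
    cfg = sd.ActivitySimConfig(
        n_flies=8, n_days=14, schedule=ld_12_12,
        peaks=[sd.ActivityPeak(10.0, 2.0, 10.0)],
        baseline=2.0, dark_attenuation=0.3, seed=42,
    )
    return sd.simulate_activity(cfg)


@pytest.fixture(scope="session")
def noiseless_cq():
    """Zero-noise Cq table for one cycling gene peaking at ZT 14."""
    cfg = sd.QpcrSimConfig(
        genes=[sd.GeneSpec("per", mesor=1.0, amplitude=0.5, peak_zt=14.0)],
        tech_sd=0.0, bio_sd=0.0, seed=5,
    )
    return sd.simulate_qpcr(cfg)


def random_dna(rng: np.random.Generator, length: int) -> str:
    table = bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
    return bytes(rng.integers(0, 4, size=length, dtype=np.uint8)).translate(table).decode()
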
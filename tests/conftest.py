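import numpy as np
import pytest

from afburden import synthetic as syn


def make_record(rhythm: str, seed: int, hr: float = 70.0, noise: float = 0.0,
                fs: float = 200.0) -> syn.ECGRecord:
    rr = syn.generate_rr_series(rhythm if rhythm != "NOISE" else "SR", 30.0, hr,
                                seed=seed)
    level = noise if rhythm != "NOISE" else max(noise, 3.0)
    return syn.synthesize_ecg(rr, rhythm if rhythm != "NOISE" else "SR",
                              noise_level=level, fs=fs, seed=seed + 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sr_af_rr_series():
    """150 SR and 150 AF RR series over a 50-110 bpm range."""
    rng = np.random.default_rng(7)
    out = {"SR": [], "AF": []}
    for _ in range(150):
        for rhythm in out:
            hr = rng.uniform(50, 110)
            out[rhythm].append(
                syn.generate_rr_series(rhythm, 30.0, hr, seed=int(rng.integers(2**31)))
            )
    return out
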
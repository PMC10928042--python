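import numpy as np
import pytest

from mbdwi import (
    AcquisitionProtocol, SignalDecay,
    dki_signal, froc_signal, ivim_signal, sem_signal,
)


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


def decay_from_model(model: str, params, b_values, protocol=None) -> SignalDecay:
    """Noise-free relative decay of one model over the given b-values."""
    b = np.asarray(b_values, dtype=float)
    if model == "ivim":
        s = ivim_signal(params, b)
    elif model == "dki":
        s = dki_signal(params, b, warn_validity=False)
    elif model == "sem":
        s = sem_signal(params, b)
    elif model == "froc":
        s = froc_signal(params, b, protocol)
    else:
        raise ValueError(model)
    return SignalDecay(b, s)


def noisy_decay(s_rel: np.ndarray, b: np.ndarray, snr: float, averages, rng,
                s0: float = 1000.0) -> SignalDecay:
    """Rician-corrupted decay normalised by its own noisy S(0)."""
    avgs = np.asarray(averages, dtype=float)
    sigma = (s0 / snr) * np.sqrt(avgs[0] / avgs)
    re = s0 * s_rel + rng.normal(0, 1, s_rel.shape) * sigma
    im = rng.normal(0, 1, s_rel.shape) * sigma
    mag = np.hypot(re, im)
    rel = np.clip(mag / mag[0], 1e-6, None)
    rel[0] = 1.0
    return SignalDecay(b, rel)
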
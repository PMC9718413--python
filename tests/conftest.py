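import numpy as np
import pytest

from mmnfb import signal_core as sc


def make_epoch(trial_type="standard", deflection_uv=0.0, sample_rate=500.0,
               latency_ms=170.0, width_ms=40.0, offset_uv=0.0):
    """Construct a baseline-corrected epoch with an optional Gaussian
    deflection (negative for deflection_uv > 0) inside the MMN window."""
    n_pre = int(round(sc.EPOCH_PRE_MS * sample_rate / 1000.0))
    n_post = int(round(sc.EPOCH_POST_MS * sample_rate / 1000.0))
    t = (np.arange(-n_pre, n_post)) * 1000.0 / sample_rate
    g = np.exp(-0.5 * ((t - latency_ms) / width_ms) ** 2)
    g[t < 0] = 0.0  # keep the baseline segment exactly flat
    x = offset_uv - deflection_uv * g
    ep = sc.Epoch(x, np.zeros_like(x), trial_type, sample_rate)
    ep = sc.baseline_correct(ep)
    ep.is_artifact = False
    return ep


@pytest.fixture
def epoch_factory():
    return make_epoch
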
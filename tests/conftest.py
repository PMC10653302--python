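import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 3-channel, 2-class, 400-sample labeled recording."""
    from harnet import RawRecording

    n = 400
    t = np.arange(n) / 50.0
    labels = np.repeat([0, 1, 0, 1], n // 4)
    freqs = np.where(labels == 0, 2.0, 6.0)
    values = np.stack([np.sin(2 * np.pi * freqs * t + p) for p in (0.0, 1.0, 2.0)])
    values += rng.normal(0, 0.1, values.shape)
    return RawRecording(values, 50.0, labels)


@pytest.fixture
def tiny_window_set(rng):
    """60 windows, 3 channels, length 20, 2 classes — fast to train on."""
    from harnet import WindowSet

    W, C, L = 60, 3, 20
    labels = np.tile([0, 1], W // 2)
    t = np.arange(L) / 50.0
    freqs = np.where(labels == 0, 3.0, 10.0)
    values = np.sin(2 * np.pi * freqs[:, None, None] * t[None, None, :]
                    + rng.uniform(0, 2 * np.pi, (W, C, 1)))
    values += rng.normal(0, 0.05, values.shape)
    return WindowSet(values, labels, np.arange(W) * L, 2, 50.0, L, 0.0)


@pytest.fixture
def tiny_configs():
    """A deliberately small architecture for fast training tests."""
    from harnet import EncoderConfig, SEConfig

    se = SEConfig(conv_kernel_sizes=(3,), conv_out_channels=(8,))
    enc = EncoderConfig(d_model=8, n_heads=2, n_layers=1, ffn_dim=16,
                        dropout=0.0, slide_radius=2, mask_fraction=0.5)
    return se, enc
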
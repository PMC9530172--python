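import numpy as np
import pytest

import starchshg as s


@pytest.fixture
def tiny_scene():
    """A small, fast scene: 3 chloroplasts on a 64x64 field."""
    return s.SceneConfig(
        image_shape=(64, 64), n_chloroplasts=3, chloroplast_axes_px=(6.0, 9.0),
        rng_seed=0,
    )


@pytest.fixture
def optics():
    return s.OpticsConfig()


@pytest.fixture
def optics_clean():
    """Optics with the 590 nm contaminant switched off (zero leakage)."""
    return s.OpticsConfig(leak590_amplitude=0.0)


@pytest.fixture
def wavelengths():
    return np.arange(520.0, 701.0, 1.0)


def tpf_image(arr, dwell_ms=0.016):
    return s.ChannelImage(np.asarray(arr, dtype=np.int64), "TPF", dwell_ms)


def shg_image(arr, dwell_ms=0.128):
    return s.ChannelImage(np.asarray(arr, dtype=np.int64), "SHG", dwell_ms)
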
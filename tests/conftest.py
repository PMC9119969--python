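import warnings

import numpy as np
import pytest

from pvrassays.frames import FilterConfig, ImageFrame
from pvrassays.synthetic import FluorFieldSpec, PhaseFieldSpec, generate_fluor_field, generate_phase_field


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    """Blank/full synthetic fields legitimately trigger single-class warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="single-class entropy map")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return FilterConfig()


@pytest.fixture
def small_phase_field():
    """128x128 field at 30% confluence with its ground truth."""
    return generate_phase_field(PhaseFieldSpec(height=128, width=128, confluence_target=30.0, seed=7))


@pytest.fixture
def small_fluor_field():
    """Compact two-channel field: 40 well-separated nuclei, 50% marker-positive."""
    spec = FluorFieldSpec(height=320, width=320, n_nuclei=40, positive_fraction=0.5, seed=11)
    return generate_fluor_field(spec)


def brute_force_local_entropy(image: np.ndarray, window: int) -> np.ndarray:
    """Independent per-window histogram-entropy computation (base 2)."""
    quantised = np.clip(np.round(image), 0, 255).astype(int)
    pad = window // 2
    padded = np.pad(quantised, pad, mode="symmetric")
    out = np.zeros(image.shape, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            win = padded[i : i + window, j : j + window].ravel()
            counts = np.bincount(win, minlength=256)
            p = counts[counts > 0] / win.size
            out[i, j] = float(-(p * np.log2(p)).sum())
    return out


@pytest.fixture
def entropy_oracle():
    return brute_force_local_entropy
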
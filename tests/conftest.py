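import numpy as np
import pytest

from fidcraft import AcquisitionParams, SpectralLine, simulate_fid


@pytest.fixture
def small_params() -> AcquisitionParams:
    """A small acquisition grid for fast unit tests."""
    return AcquisitionParams(
        spectrometer_freq=500.0, sweep_width=2000.0, n_points=2048,
        carrier_ppm=4.7,
    )


@pytest.fixture
def single_line_fid(small_params):
    """Noiseless single damped sinusoid with known parameters."""
    line = SpectralLine("probe", center_ppm=4.7 + 50 / 500, amplitude=1.3,
                        decay=5.0, phase=0.3)
    return line, simulate_fid([line], small_params)


def two_class_labels(n_per_class: int = 20) -> np.ndarray:
    return np.array([0] * n_per_class + [1] * n_per_class, dtype=float)
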
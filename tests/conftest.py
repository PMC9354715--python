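import numpy as np
import pytest

from pumpprobe.synthetic import (
    AcquisitionMetadata,
    NoiseSpec,
    PhantomSpec,
    generate_phantom,
    render_stack,
)
from pumpprobe.ta_model import default_irf, default_models


@pytest.fixture(scope="session")
def irf():
    return default_irf()


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def small_metadata():
    """64×64 px over the standard 212 µm field; full default delay grid."""
    return AcquisitionMetadata(width_px=64, height_px=64)


@pytest.fixture(scope="session")
def two_region_phantom(small_metadata):
    return generate_phantom(
        PhantomSpec(layout="two_region_interface", metadata=small_metadata, seed=1)
    )


@pytest.fixture(scope="session")
def two_region_stack(two_region_phantom, small_metadata):
    """Noiseless render of the two-region interface phantom."""
    return render_stack(two_region_phantom, metadata=small_metadata)


def brute_force_convolved(model, irf, delays_ps, t0_ps=0.0):
    """Independent oracle: discrete convolution of the ideal decay with a
    sampled Gaussian kernel (step σ/200, well inside the σ/20 requirement so
    the oracle's own sampling error is negligible against the 1e-3 band),
    interpolated onto the query delays."""
    from pumpprobe.ta_model import decay_trace

    delays = np.asarray(delays_ps, dtype=float)
    s = irf.sigma_ps
    step = s / 200.0
    lo = min(float(delays.min() - t0_ps), 0.0) - 10.0 * s
    hi = max(float(delays.max() - t0_ps), 0.0) + 10.0 * s
    grid = np.arange(lo, hi + step, step)
    decay = decay_trace(model, grid)
    half = int(np.ceil(8.0 * s / step))
    kern_t = np.arange(-half, half + 1) * step
    kern = np.exp(-(kern_t**2) / (2.0 * s**2))
    kern /= kern.sum()
    conv = np.convolve(decay, kern, mode="same")
    return np.interp(delays - t0_ps, grid, conv)
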
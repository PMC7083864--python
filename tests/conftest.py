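import numpy as np
import pytest

from astroseg.filters import build_filter_bank


@pytest.fixture(scope="session")
def default_bank():
    return build_filter_bank()


@pytest.fixture(scope="session")
def small_bank():
    """Cheap bank for oracle comparisons: 1 scale, 6 orientations."""
    return build_filter_bank(n_scales=1, n_orientations=6, base_kernel_size=9)


@pytest.fixture(scope="session")
def profile_bank():
    from astroseg.postprocess import build_profile_bank

    return build_profile_bank()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def naive_correlate_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force nested-loop correlation with reflect padding.

    Independent oracle for apply_bank: O(N^2 K^2) per kernel, no FFT.
    """
    k = kernel.shape[0]
    pad = k // 2
    padded = np.pad(image, pad, mode="reflect")
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            acc = 0.0
            for u in range(k):
                for v in range(k):
                    acc += padded[i + u, j + v] * kernel[u, v]
            out[i, j] = acc
    return out


def fast_reference_correlate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Windowed-sum correlation oracle (no FFT, no scipy.signal)."""
    k = kernel.shape[0]
    pad = k // 2
    padded = np.pad(image, pad, mode="reflect")
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = float(np.sum(padded[i:i + k, j:j + k] * kernel))
    return out
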
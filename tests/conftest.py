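import numpy as np
import pytest

from lowfield_sr.kspace import DegradationConfig
from lowfield_sr.model import ModelConfig
from lowfield_sr.phantom import PhantomConfig, generate_phantom, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """A small but structurally complete network for fast training tests."""
    return ModelConfig(
        n_blocks=2,
        layers_per_block=2,
        growth=8,
        bottleneck_out=32,
        deconv_out=32,
        initial_conv_out=8,
    )


@pytest.fixture
def phantom_pair():
    """One deterministic HR/LR phantom pair at default study conditions."""
    hr = generate_phantom(PhantomConfig(), seed=42)
    return make_pair(hr, DegradationConfig(), seed=43)


def band_limited_image(seed: int = 7, size: int = 128) -> np.ndarray:
    """A non-negative image whose k-space support fits the half-size grid.

    The phantom is low-passed in the complex domain (crop + zero-pad of its
    centered spectrum), then affinely mapped into (0, 1]; the affine map only
    changes the DC coefficient, so the result stays band-limited — and being
    strictly positive, the magnitude step of the degradation is the identity
    on it. Such images are exact fixed points of the degrade/zero-fill cycle.

    The kept support is the symmetric window -(n/2-1) .. n/2-1 (one short of
    Nyquist): taking the real part conjugate-reflects the spectrum, so a
    support including -n/2 but not +n/2 would leak outside the crop window.
    """
    from lowfield_sr.kspace import central_crop, fft2c, ifft2c, zero_pad

    n = size // 2
    x = generate_phantom(PhantomConfig(size=(size, size)), seed=seed)
    k = zero_pad(central_crop(fft2c(x), (n - 1, n - 1)), (size, size))
    r = ifft2c(k).real
    r = r - r.min() + 0.01
    return r / r.max()


@pytest.fixture
def band_limited_pair():
    """A noise-free pair whose HR k-space support fits the LR grid.

    Such images are fixed points of crop-then-pad, so zero-filling
    reconstructs them exactly.
    """
    cfg = DegradationConfig(noise_rho_range=(0.0, 0.0))
    return make_pair(band_limited_image(7), cfg, seed=1)


def dft2c_oracle(x: np.ndarray) -> np.ndarray:
    """O(N^4) direct-sum centered orthonormal 2D DFT (independent oracle)."""
    x = np.asarray(x, dtype=complex)
    H, W = x.shape
    m = np.arange(H) - H // 2
    n = np.arange(W) - W // 2
    out = np.zeros((H, W), dtype=complex)
    for pi, p in enumerate(m):
        for qi, q in enumerate(n):
            phase = np.exp(-2j * np.pi * (p * m[:, None] / H + q * n[None, :] / W))
            out[pi, qi] = np.sum(x * phase)
    return out / np.sqrt(H * W)


def idft2c_oracle(k: np.ndarray) -> np.ndarray:
    """O(N^4) direct-sum inverse of :func:`dft2c_oracle`."""
    k = np.asarray(k, dtype=complex)
    H, W = k.shape
    m = np.arange(H) - H // 2
    n = np.arange(W) - W // 2
    out = np.zeros((H, W), dtype=complex)
    for mi, mm in enumerate(m):
        for ni, nn in enumerate(n):
            phase = np.exp(2j * np.pi * (mm * m[:, None] / H + nn * n[None, :] / W))
            out[mi, ni] = np.sum(k * phase)
    return out / np.sqrt(H * W)
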
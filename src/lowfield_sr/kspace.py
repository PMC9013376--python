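"""Acquisition-consistent k-space degradation operators for 2D MR images.

Low-resolution MR acquisition is modelled in the spatial-frequency domain:
the high-resolution image is Fourier transformed, only the central
(low-frequency) block of k-space is retained — mimicking a shorter k-space
sweep — complex Gaussian noise is added to emulate the low SNR of low-field
scanners, and an inverse FFT on the small grid yields the noisy
low-resolution image:

    y = |F_LR^{-1} ( D F_HR x + n )|

where ``D`` selects the centered low-frequency block. The classical
zero-filling reconstruction (embedding the measured block in a larger grid
of zeros before the inverse FFT) is implemented here as the baseline the
learned reconstruction is compared against.

Conventions
-----------
* Centered, orthonormal FFTs: the DC coefficient sits at index
  ``(H//2, W//2)``; Parseval's identity holds exactly.
* The even-size crop window is the half-open centered block
  ``[N/2 - n/2, N/2 + n/2)``, i.e. frequencies ``-n/2 .. n/2 - 1`` are kept.
* A grid-size rescaling factor ``sqrt(h*w / (H*W))`` is applied after
  cropping (and its inverse after padding) so a noise-free constant image
  maps to the same constant at every resolution.
* The complex-to-real step takes the magnitude, matching how MR images are
  displayed and producing the characteristic Rician-like image-domain noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegradationConfig",
    "fft2c",
    "ifft2c",
    "central_crop",
    "zero_pad",
    "add_complex_noise",
    "degrade",
    "zero_fill_sr",
    "resize_via_kspace",
    "KSpaceDegrader",
]

_MIN_SIZE = 8


def _check_image(a: np.ndarray, name: str = "image", min_size: int = _MIN_SIZE) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {a.shape}")
    if a.shape[0] < min_size or a.shape[1] < min_size:
        raise ValueError(f"{name} must be at least {min_size}x{min_size}, got {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite values")
    return a


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2D FFT (DC at ``(H//2, W//2)``)."""
    img = _check_image(img, "image")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`; returns a complex image."""
    k = _check_image(k, "k-space grid")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


def _crop_slices(src: tuple[int, int], dst: tuple[int, int]) -> tuple[slice, slice]:
    (H, W), (h, w) = src, dst
    r0 = H // 2 - h // 2
    c0 = W // 2 - w // 2
    return slice(r0, r0 + h), slice(c0, c0 + w)


def central_crop(k: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Keep the centered ``target`` block of a k-space grid (operator D)."""
    k = np.asarray(k)
    h, w = target
    if h > k.shape[0] or w > k.shape[1]:
        raise ValueError(f"crop target {target} exceeds source shape {k.shape}")
    rs, cs = _crop_slices(k.shape, (h, w))
    return k[rs, cs].copy()


def zero_pad(k: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Embed a k-space grid at the centered position of a larger zero grid."""
    k = np.asarray(k)
    H, W = target
    if H < k.shape[0] or W < k.shape[1]:
        raise ValueError(f"pad target {target} smaller than source shape {k.shape}")
    out = np.zeros((H, W), dtype=complex)
    rs, cs = _crop_slices((H, W), k.shape)
    out[rs, cs] = k
    return out


def add_complex_noise(k: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add circular complex Gaussian noise: Re and Im parts each N(0, sigma^2/2).

    The total per-coefficient noise power is ``sigma**2``. Deterministic
    given ``seed``.
    """
    k = np.asarray(k)
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return k.copy()
    rng = np.random.default_rng(seed)
    s = sigma / np.sqrt(2.0)
    noise = rng.normal(0.0, s, k.shape) + 1j * rng.normal(0.0, s, k.shape)
    return k + noise


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the HR -> LR k-space degradation.

    ``noise_rho_range`` is the per-image relative noise level: the complex
    noise standard deviation is ``rho * RMS(|cropped k-space|)`` with ``rho``
    drawn uniformly from this range. The default range stands in for the
    unpublished noise levels of real low-field acquisitions and should be
    treated as a tunable, not a constant.
    """

    lr_size: tuple[int, int] = (64, 64)
    hr_size: tuple[int, int] = (128, 128)
    noise_rho_range: tuple[float, float] = (0.02, 0.20)
    magnitude_output: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.lr_size
        H, W = self.hr_size
        if h > H or w > W:
            raise ValueError(f"lr_size {self.lr_size} exceeds hr_size {self.hr_size}")
        lo, hi = self.noise_rho_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid noise_rho_range {self.noise_rho_range}")


def _scale(src: tuple[int, int], dst: tuple[int, int]) -> float:
    # keeps a constant image constant across grid sizes (orthonormal FFTs)
    return float(np.sqrt((dst[0] * dst[1]) / (src[0] * src[1])))


def degrade(
    hr: np.ndarray,
    cfg: DegradationConfig | None = None,
    seed: int = 0,
    rho: float | None = None,
    _complex_output: bool = False,
) -> np.ndarray:
    """Simulate low-resolution acquisition of a high-resolution image.

    Crops the centered LR block of the HR image's k-space, rescales so that
    constants are preserved, adds circular complex Gaussian noise of level
    ``rho * RMS(|cropped coefficients|)``, and inverse transforms. When
    ``rho`` is None, it is drawn uniformly from ``cfg.noise_rho_range``
    (deterministically in ``seed``).
    """
    cfg = cfg or DegradationConfig()
    hr = _check_image(hr, "hr image")
    if hr.shape != tuple(cfg.hr_size):
        raise ValueError(f"hr image shape {hr.shape} != cfg.hr_size {cfg.hr_size}")
    k = central_crop(fft2c(hr), cfg.lr_size) * _scale(cfg.hr_size, cfg.lr_size)
    rng = np.random.default_rng(seed)
    if rho is None:
        lo, hi = cfg.noise_rho_range
        rho = float(rng.uniform(lo, hi))
    if rho < 0:
        raise ValueError(f"rho must be non-negative, got {rho}")
    sigma = rho * float(np.sqrt(np.mean(np.abs(k) ** 2)))
    noise_seed = int(rng.integers(0, 2**31 - 1))
    k = add_complex_noise(k, sigma, noise_seed)
    lr = ifft2c(k)
    if _complex_output or not cfg.magnitude_output:
        return lr
    return np.abs(lr)


def zero_fill_sr(lr: np.ndarray, target: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Zero-filling reconstruction: the classical interpolation baseline.

    Embeds the LR image's k-space in a larger zero grid and inverse
    transforms, returning the magnitude image at ``target`` size.
    """
    lr = _check_image(lr, "lr image")
    if target[0] < lr.shape[0] or target[1] < lr.shape[1]:
        raise ValueError(f"target {target} smaller than input {lr.shape}")
    k = zero_pad(fft2c(lr), target) * _scale(lr.shape, target)
    return np.abs(ifft2c(k))


def resize_via_kspace(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Resize by cropping/padding centered k-space, per dimension.

    A dimension shrinks by discarding its outer frequencies and grows by
    zero-padding them; mixed targets (crop rows, pad columns) are supported.
    """
    img = _check_image(img, "image")
    k = fft2c(img)
    inter = (min(img.shape[0], target[0]), min(img.shape[1], target[1]))
    k = central_crop(k, inter)
    k = zero_pad(k, target)
    k = k * _scale(img.shape, target)
    return np.abs(ifft2c(k))


class KSpaceDegrader:
    """Stateless transformer applying the k-space degradation to a stack of images.

    sklearn-compatible: ``fit`` is a no-op, ``transform`` maps an array of HR
    images ``(n, H, W)`` to LR images ``(n, h, w)``; per-image noise levels
    are drawn from ``noise_rho_range`` deterministically in ``random_state``.
    """

    def __init__(
        self,
        lr_size: tuple[int, int] = (64, 64),
        hr_size: tuple[int, int] = (128, 128),
        noise_rho_range: tuple[float, float] = (0.02, 0.20),
        random_state: int = 0,
    ):
        self.lr_size = lr_size
        self.hr_size = hr_size
        self.noise_rho_range = noise_rho_range
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "lr_size": self.lr_size,
            "hr_size": self.hr_size,
            "noise_rho_range": self.noise_rho_range,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "KSpaceDegrader":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> DegradationConfig:
        return DegradationConfig(
            lr_size=tuple(self.lr_size),
            hr_size=tuple(self.hr_size),
            noise_rho_range=tuple(self.noise_rho_range),
        )

    def fit(self, X=None, y=None) -> "KSpaceDegrader":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        cfg = self._config()
        out = np.empty((X.shape[0],) + tuple(self.lr_size))
        for i, img in enumerate(X):
            from .seeding import stream_seed

            out[i] = degrade(img, cfg, seed=stream_seed(self.random_state, f"degrade/{i}"))
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
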
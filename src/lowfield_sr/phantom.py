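"""Synthetic brain-like phantoms and paired HR/LR training data.

Real training corpora for MR super-resolution are built from clinical
databases; this module provides a self-contained substitute: piecewise-smooth
head phantoms (nested ellipses with smoothed boundaries and low-frequency
intensity texture) that exercise the same degradation and training pipeline
without any external download. Intensity-level diversity across phantoms
stands in for the contrast variety (T1/T2/FLAIR) of a real database; no
tissue-relaxation physics is modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .kspace import DegradationConfig, degrade
from .seeding import stream_rng, stream_seed

__all__ = [
    "PhantomConfig",
    "ImagePair",
    "PatchPair",
    "generate_phantom",
    "make_pair",
    "build_dataset",
    "load_dataset",
    "extract_patches",
    "patch_arrays",
]

HR_PATCH = 32
LR_PATCH = 16


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and texture parameters of the synthetic head phantom."""

    size: tuple[int, int] = (128, 128)
    n_inner_ellipses: tuple[int, int] = (3, 8)
    intensity_levels: tuple[float, float] = (0.15, 1.0)
    smooth_sigma: float = 1.0
    texture_amp: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size[0] < 8 or self.size[1] < 8:
            raise ValueError(f"degenerate phantom size {self.size}")
        lo, hi = self.n_inner_ellipses
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid n_inner_ellipses range {self.n_inner_ellipses}")
        if self.smooth_sigma < 0 or self.texture_amp < 0:
            raise ValueError("smooth_sigma and texture_amp must be non-negative")


def _ellipse_mask(shape, center, axes, angle, yy, xx):
    cy, cx = center
    ay, ax = axes
    c, s = np.cos(angle), np.sin(angle)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def generate_phantom(cfg: PhantomConfig | None = None, seed: int | None = None) -> np.ndarray:
    """Generate one piecewise-smooth head-like image in [0, 1].

    The head (outer "skull" ellipse) is filled with a base intensity and
    always lies inside the frame; 0 outside. Inner ellipses paint their own
    intensity levels, boundaries are optionally Gaussian-smoothed inside the
    head, and a low-frequency multiplicative texture modulates the tissue.
    Deterministic given the seed.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    H, W = cfg.size
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    lo, hi = cfg.intensity_levels

    # head ellipse: large enough that >=20% of pixels are tissue
    cy = H / 2 + rng.uniform(-0.02, 0.02) * H
    cx = W / 2 + rng.uniform(-0.02, 0.02) * W
    ay = rng.uniform(0.36, 0.44) * H
    ax = rng.uniform(0.30, 0.40) * W
    angle = rng.uniform(-0.2, 0.2)
    head = _ellipse_mask(cfg.size, (cy, cx), (ay, ax), angle, yy, xx)

    base = rng.uniform(max(lo, 0.3), hi * 0.8)
    img = np.where(head, base, 0.0)

    n_inner = int(rng.integers(cfg.n_inner_ellipses[0], cfg.n_inner_ellipses[1] + 1))
    for _ in range(n_inner):
        e_ay = rng.uniform(0.05, 0.35) * ay
        e_ax = rng.uniform(0.05, 0.35) * ax
        # keep inner structures well inside the head
        e_cy = cy + rng.uniform(-0.5, 0.5) * ay
        e_cx = cx + rng.uniform(-0.5, 0.5) * ax
        e_angle = rng.uniform(-np.pi, np.pi)
        level = rng.uniform(lo, hi)
        mask = _ellipse_mask(cfg.size, (e_cy, e_cx), (e_ay, e_ax), e_angle, yy, xx) & head
        img[mask] = level

    if cfg.smooth_sigma > 0:
        img = gaussian_filter(img, cfg.smooth_sigma)
    if cfg.texture_amp > 0:
        field = gaussian_filter(rng.standard_normal((H, W)), sigma=min(H, W) / 8)
        peak = np.max(np.abs(field))
        if peak > 0:
            field = field / peak
        img = img * (1.0 + cfg.texture_amp * field)
    img = np.clip(img, 0.0, 1.0)
    m = img.max()
    if m > 0:  # per-image max normalization: the HR intensity contract
        img = img / m
    return img


@dataclass(frozen=True)
class ImagePair:
    """A noise-free HR image and its reproducible noisy LR counterpart."""

    hr: np.ndarray
    lr: np.ndarray
    noise_rho: float
    seed: int

    def __post_init__(self) -> None:
        if self.lr.shape[0] > self.hr.shape[0] or self.lr.shape[1] > self.hr.shape[1]:
            raise ValueError("lr image larger than hr image")


@dataclass(frozen=True)
class PatchPair:
    """Aligned 32x32 HR / 16x16 LR training patches; HR origin is even."""

    hr_patch: np.ndarray
    lr_patch: np.ndarray
    hr_origin: tuple[int, int]

    def __post_init__(self) -> None:
        r, c = self.hr_origin
        if r % 2 or c % 2:
            raise ValueError(f"hr_origin must have even components, got {self.hr_origin}")


def make_pair(hr: np.ndarray, dcfg: DegradationConfig, seed: int) -> ImagePair:
    """Degrade one HR image into its LR counterpart, recording rho."""
    rng = np.random.default_rng(seed)
    lo, hi = dcfg.noise_rho_range
    rho = float(rng.uniform(lo, hi))
    lr = degrade(hr, dcfg, seed=seed)
    return ImagePair(hr=hr, lr=lr, noise_rho=rho, seed=seed)


def extract_patches(pair: ImagePair, k: int, seed: int = 0) -> list[PatchPair]:
    """Sample ``k`` aligned patch pairs at uniformly random even HR origins.

    LR patches are cut from the already-degraded full LR image at halved
    coordinates — degrading a small patch in its own k-space would be a
    different operator (periodic-boundary leakage) than the full-image
    acquisition model. Sampling is with replacement.
    """
    H, W = pair.hr.shape
    if H < HR_PATCH or W < HR_PATCH:
        raise ValueError(f"hr image {pair.hr.shape} smaller than {HR_PATCH}x{HR_PATCH}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(k):
        r = 2 * int(rng.integers(0, (H - HR_PATCH) // 2 + 1))
        c = 2 * int(rng.integers(0, (W - HR_PATCH) // 2 + 1))
        hr_p = pair.hr[r : r + HR_PATCH, c : c + HR_PATCH].copy()
        lr_p = pair.lr[r // 2 : r // 2 + LR_PATCH, c // 2 : c // 2 + LR_PATCH].copy()
        out.append(PatchPair(hr_patch=hr_p, lr_patch=lr_p, hr_origin=(r, c)))
    return out


def patch_arrays(patches: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patch pairs into (X_lr, y_hr) arrays of shape (n, h, w)."""
    X = np.stack([p.lr_patch for p in patches])
    y = np.stack([p.hr_patch for p in patches])
    return X, y


def build_dataset(
    n: int,
    pcfg: PhantomConfig | None = None,
    dcfg: DegradationConfig | None = None,
    seed: int = 0,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    out_dir: str | Path | None = None,
) -> dict:
    """Generate ``n`` HR/LR pairs with a phantom-level train/val/test split.

    The split is assigned per phantom (never per patch), so no image
    contributes to more than one split. Returns a manifest dict recording
    per-image seeds, noise levels and split membership; when ``out_dir`` is
    given, writes ``hr/*.npy``, ``lr/*.npy`` and ``manifest.yaml``.
    Rebuilding from the same master seed is byte-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    pcfg = pcfg or PhantomConfig()
    dcfg = dcfg or DegradationConfig()

    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    n_test = n - n_train - n_val
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    order = stream_rng(seed, "split").permutation(n)
    assignment = [None] * n
    for slot, idx in enumerate(order):
        assignment[idx] = labels[slot]

    entries = []
    pairs = []
    for i in range(n):
        p_seed = stream_seed(seed, f"phantom/{i}")
        d_seed = stream_seed(seed, f"degrade/{i}")
        hr = generate_phantom(pcfg, seed=p_seed)
        pair = make_pair(hr, dcfg, seed=d_seed)
        pairs.append(pair)
        entries.append(
            {
                "id": f"img{i:05d}",
                "phantom_seed": int(p_seed),
                "degrade_seed": int(d_seed),
                "noise_rho": float(pair.noise_rho),
                "split": assignment[i],
            }
        )

    manifest = {
        "n": n,
        "master_seed": int(seed),
        "split_fractions": list(split),
        "phantom_config": dataclasses.asdict(pcfg),
        "degradation_config": dataclasses.asdict(dcfg),
        "images": entries,
    }
    # tuples -> lists for clean YAML round-trips
    manifest = yaml.safe_load(yaml.safe_dump(manifest))

    if out_dir is not None:
        out = Path(out_dir)
        (out / "hr").mkdir(parents=True, exist_ok=True)
        (out / "lr").mkdir(parents=True, exist_ok=True)
        for e, pair in zip(entries, pairs):
            np.save(out / "hr" / f"{e['id']}.npy", pair.hr)
            np.save(out / "lr" / f"{e['id']}.npy", pair.lr)
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    manifest["_pairs"] = pairs  # in-memory convenience, not serialized
    return manifest


def load_dataset(path: str | Path, split: str | None = None) -> list[ImagePair]:
    """Load stored HR/LR pairs, optionally filtered by split label."""
    path = Path(path)
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    pairs = []
    for e in manifest["images"]:
        if split is not None and e["split"] != split:
            continue
        hr = np.load(path / "hr" / f"{e['id']}.npy")
        lr = np.load(path / "lr" / f"{e['id']}.npy")
        pairs.append(ImagePair(hr=hr, lr=lr, noise_rho=e["noise_rho"], seed=e["degrade_seed"]))
    return pairs
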
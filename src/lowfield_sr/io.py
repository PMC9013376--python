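"""Image and configuration I/O.

NPY is the lossless interchange format; PNG previews are quantized to
16 bits with the scaling recorded alongside; NIfTI volumes can contribute
2D slices. Every run directory gets a frozen ``config.yaml`` echo so the
stage can be re-run bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

__all__ = ["load_image", "save_image", "save_png_preview", "write_config", "read_config"]


def load_image(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Load a 2D image from .npy, .png, or a .nii/.nii.gz slice."""
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix == ".npy":
        img = np.load(path)
    elif suffix in (".nii", ".nii.gz"):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        idx = vol.shape[-1] // 2 if slice_index is None else slice_index
        img = vol[..., idx] if vol.ndim == 3 else vol
    elif suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=float)
        img = arr / arr.max() if arr.max() > 0 else arr
    else:
        raise ValueError(f"unsupported image format: {path}")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    return img


def save_image(path: str | Path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, np.asarray(img))


def save_png_preview(path: str | Path, img: np.ndarray) -> float:
    """Write a 16-bit PNG preview; returns the scale used (max intensity)."""
    from PIL import Image

    img = np.asarray(img, dtype=float)
    scale = float(img.max()) if img.max() > 0 else 1.0
    q = np.clip(img / scale, 0.0, 1.0)
    arr = (q * 65535.0 + 0.5).astype(np.uint16)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="I;16").save(path)
    return scale


def write_config(path: str | Path, cfg: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
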
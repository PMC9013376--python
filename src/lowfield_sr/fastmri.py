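"""Optional ingestion of fastMRI-dialect HDF5 volumes.

This is a secondary data pathway: the packaged pipeline runs entirely on
synthetic phantoms, but when real multi-slice brain volumes in the fastMRI
HDF5 layout are available locally, this module extracts magnitude slices,
resizes them to the working HR grid via k-space crop/pad, and normalizes
each slice by its own maximum — after which they enter the same pairing
pipeline as phantoms. Requires ``h5py``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .kspace import resize_via_kspace

__all__ = ["load_slices"]

_RECON_KEYS = ("reconstruction_rss", "reconstruction_esc")


def load_slices(
    path: str | Path,
    hr_size: tuple[int, int] = (128, 128),
    max_slices: int | None = None,
) -> list[np.ndarray]:
    """Read magnitude slices from one fastMRI HDF5 file as normalized HR images.

    Prefers the stored magnitude reconstructions; falls back to an inverse
    FFT of single-coil k-space. Each slice is resized to ``hr_size`` by
    centered k-space crop/pad and divided by its own maximum.
    """
    import h5py

    slices = []
    with h5py.File(path, "r") as f:
        vol = None
        for key in _RECON_KEYS:
            if key in f:
                vol = np.asarray(f[key])
                break
        if vol is None and "kspace" in f:
            k = np.asarray(f["kspace"])
            if k.ndim != 3:
                raise ValueError(
                    f"unsupported k-space layout {k.shape}; expected single-coil (slices, H, W)"
                )
            vol = np.abs(np.fft.fftshift(np.fft.ifft2(k, norm="ortho"), axes=(-2, -1)))
        if vol is None:
            raise ValueError(f"no recognised image data in {path}")
    for i, sl in enumerate(vol):
        if max_slices is not None and i >= max_slices:
            break
        img = resize_via_kspace(np.asarray(sl, dtype=float), hr_size)
        m = img.max()
        slices.append(img / m if m > 0 else img)
    return slices
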
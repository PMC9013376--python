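"""Image-quality evaluation: PSNR/SSIM, zero-filling baseline vs. network.

The comparison protocol mirrors the standard super-resolution benchmark:
for every held-out HR/LR pair, reconstruct the HR image (a) by zero-filling
the LR k-space and (b) by the trained network, then score both against the
noise-free HR reference with PSNR and SSIM. All intensities live in [0, 1]
(per-image max normalization upstream), so ``data_range`` defaults to 1.0
and is recorded in every report; network outputs are clamped to [0, 1]
before scoring, since the references live there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.metrics import structural_similarity

from .kspace import zero_fill_sr
from .phantom import ImagePair

__all__ = ["MetricsReport", "psnr", "ssim", "evaluate"]


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB.

    Returns ``math.inf`` (the identical-image sentinel) when MSE is zero.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Mean structural similarity with a Gaussian window (11x11, sigma 1.5)."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if min(ref.shape) < win_size:
        raise ValueError(f"image {ref.shape} smaller than SSIM window {win_size}")
    return float(
        structural_similarity(
            ref,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=sigma,
            win_size=win_size,
            use_sample_covariance=False,
            K1=K1,
            K2=K2,
        )
    )


@dataclass
class MetricsReport:
    """Per-image and aggregate PSNR/SSIM for each reconstruction method."""

    rows: pd.DataFrame
    data_range: float = 1.0
    ssim_win_size: int = 11

    def aggregates(self) -> pd.DataFrame:
        return self.rows.groupby("method")[["psnr", "ssim"]].agg(["mean", "std"])

    def mean(self, method: str, metric: str) -> float:
        sel = self.rows[self.rows["method"] == method][metric]
        if sel.empty:
            raise ValueError(f"no rows for method {method!r}")
        return float(sel.mean())

    def write(self, out_dir: str | Path) -> None:
        """Write per-image ``metrics.csv`` and aggregate ``summary.yaml``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "metrics.csv", index=False)
        agg = {}
        for method, grp in self.rows.groupby("method"):
            agg[str(method)] = {
                "psnr_mean": float(grp["psnr"].mean()),
                "psnr_sd": float(grp["psnr"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "ssim_mean": float(grp["ssim"].mean()),
                "ssim_sd": float(grp["ssim"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "n": int(len(grp)),
            }
        summary = {
            "config": {"data_range": self.data_range, "ssim_win_size": self.ssim_win_size},
            "methods": agg,
        }
        (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))

    @staticmethod
    def read(out_dir: str | Path) -> "MetricsReport":
        out = Path(out_dir)
        rows = pd.read_csv(out / "metrics.csv")
        summary = yaml.safe_load((out / "summary.yaml").read_text())
        return MetricsReport(
            rows=rows,
            data_range=summary["config"]["data_range"],
            ssim_win_size=summary["config"]["ssim_win_size"],
        )


def evaluate(
    pairs: list[ImagePair],
    model=None,
    data_range: float = 1.0,
    out_dir: str | Path | None = None,
) -> MetricsReport:
    """Score zero-filling (and optionally the network) against HR references.

    Network outputs are clamped to [0, 1] before scoring. Deterministic:
    contains no random element.
    """
    if not pairs:
        raise ValueError("no image pairs to evaluate")
    records = []
    for i, pair in enumerate(pairs):
        target = tuple(pair.hr.shape)
        zf = zero_fill_sr(pair.lr, target)
        records.append(
            {
                "image": f"img{i:05d}",
                "method": "zero_fill",
                "psnr": psnr(pair.hr, np.clip(zf, 0.0, 1.0), data_range),
                "ssim": ssim(pair.hr, np.clip(zf, 0.0, 1.0), data_range),
            }
        )
        if model is not None:
            sr = model.forward(pair.lr[None])[0, 0]
            sr = np.clip(np.asarray(sr, dtype=float), 0.0, 1.0)
            records.append(
                {
                    "image": f"img{i:05d}",
                    "method": "network",
                    "psnr": psnr(pair.hr, sr, data_range),
                    "ssim": ssim(pair.hr, sr, data_range),
                }
            )
    report = MetricsReport(rows=pd.DataFrame.from_records(records), data_range=data_range)
    if out_dir is not None:
        report.write(out_dir)
    return report
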
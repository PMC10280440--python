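"""Frame-similarity metrics: SSIM, PSNR, cosine similarity, mutual information.

All four metrics are computed on the luminance channel
Y = 0.299·R + 0.587·G + 0.114·B of the 8-bit frames and aggregated over a
series as mean and maximum.  SSIM uses the standard constants (k1 = 0.01,
k2 = 0.03, 255 dynamic range, 11×11 Gaussian window with sigma = 1.5); PSNR
of identical images is reported as a documented 100 dB cap; mutual
information is estimated from a 256-bin joint gray-level histogram and
reported in bits by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .core import Frame, FrameSeries

__all__ = ["ssim", "psnr", "cosine_similarity", "mutual_information",
           "evaluate_series", "MetricsReport", "luminance", "PSNR_CAP_DB"]

#: PSNR reported for a zero-MSE (identical) pair.
PSNR_CAP_DB = 100.0


def _as_pixels(a) -> np.ndarray:
    return a.pixels if isinstance(a, Frame) else np.asarray(a)


def luminance(a) -> np.ndarray:
    """Rec. 601 luma of an (H, W, 3) uint8 image, float64 in [0, 255]."""
    p = _as_pixels(a).astype(np.float64)
    if p.ndim == 3:
        return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]
    return p


def _check_shapes(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def ssim(a, b) -> float:
    """Structural similarity on luminance (Gaussian 11×11 window, sigma 1.5)."""
    ya, yb = luminance(a), luminance(b)
    _check_shapes(ya, yb)
    return float(structural_similarity(
        ya, yb, data_range=255.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio, 10·log10(255² / MSE), in dB."""
    ya, yb = luminance(a), luminance(b)
    _check_shapes(ya, yb)
    mse = float(np.mean((ya - yb) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(255.0 ** 2 / mse), PSNR_CAP_DB))


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between the flattened luminance vectors."""
    ya, yb = luminance(a).ravel(), luminance(b).ravel()
    _check_shapes(ya, yb)
    na, nb = np.linalg.norm(ya), np.linalg.norm(yb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm image")
    return float(np.dot(ya, yb) / (na * nb))


def mutual_information(a, b, bins: int = 256, unit: str = "bits") -> float:
    """Mutual information of the joint gray-level histogram.

    I(A; B) = Σ p(x,y)·log[p(x,y)/(p(x)p(y))] over ``bins`` luminance levels;
    non-negative, symmetric, and equal to the gray-level entropy H(A) when
    the images are identical.  ``unit`` is "bits" (default) or "nats".
    """
    ya = np.clip(luminance(a), 0, 255).astype(np.int64).ravel()
    yb = np.clip(luminance(b), 0, 255).astype(np.int64).ravel()
    _check_shapes(ya, yb)
    if bins != 256:
        ya = (ya * bins) // 256
        yb = (yb * bins) // 256
    joint = np.bincount(ya * bins + yb, minlength=bins * bins).astype(np.float64)
    joint /= joint.sum()
    joint = joint.reshape(bins, bins)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))
    mi = max(mi, 0.0)
    return mi / np.log(2.0) if unit == "bits" else mi


@dataclass
class MetricsReport:
    """Per-frame metric table plus mean/max aggregates."""

    per_frame: pd.DataFrame    # columns: date, ssim, psnr, cosine, mutual_information
    aggregate: dict            # metric -> {"mean": ..., "max": ...}

    def to_csv(self, path) -> None:
        self.per_frame.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"per_frame": self.per_frame.assign(
                    date=self.per_frame["date"].astype(str)).to_dict("records"),
                "aggregate": self.aggregate}


_METRICS = {"ssim": ssim, "psnr": psnr, "cosine": cosine_similarity,
            "mutual_information": mutual_information}


def evaluate_series(pred: FrameSeries, real: FrameSeries) -> MetricsReport:
    """Score a predicted series against the real one, frame by matching date."""
    if len(pred) != len(real):
        raise ValueError(f"series length mismatch: {len(pred)} vs {len(real)}")
    bad = [f"{p.date.isoformat()} vs {r.date.isoformat()}"
           for p, r in zip(pred, real) if p.date != r.date]
    if bad:
        raise ValueError("date mismatch between series: " + "; ".join(bad))
    rows = []
    for p, r in zip(pred, real):
        row = {"date": p.date}
        row.update({name: fn(p, r) for name, fn in _METRICS.items()})
        rows.append(row)
    per_frame = pd.DataFrame(rows)
    aggregate = {name: {"mean": float(per_frame[name].mean()),
                        "max": float(per_frame[name].max())}
                 for name in _METRICS}
    return MetricsReport(per_frame, aggregate)
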
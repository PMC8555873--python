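"""Image-quality indicators: Tenengrad, variance, Laplacian smoothness, SNR.

These are the no-reference scores used to compare raw and filtered vein
images: Tenengrad and variance grow with sharpness and contrast, the
Laplacian smoothness score shrinks as the image gets smoother, and the SNR
summarizes signal level against noise spread.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "QualityReport",
    "tenengrad",
    "variance",
    "std",
    "laplacian_smoothness",
    "snr",
    "quality_report",
    "write_reports_csv",
    "write_reports_json",
]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


@dataclass(frozen=True)
class QualityReport:
    tenengrad: float
    variance: float
    laplace_smoothness: float
    snr_db: float
    std: float
    name: str = ""


def _as_float(image) -> np.ndarray:
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    return np.asarray(px, dtype=np.float64)


def _require_min_size(px: np.ndarray, n: int) -> None:
    if px.shape[0] < n or px.shape[1] < n:
        raise ValueError(f"image {px.shape} smaller than the required {n}x{n} window")


def tenengrad(image) -> float:
    """Gradient-energy sharpness: sum of Gx^2 + Gy^2 over interior pixels.

    Gx and Gy are the standard 3x3 Sobel responses; no magnitude threshold
    is applied.  Larger values indicate sharper, better-focused images.
    """
    px = _as_float(image)
    _require_min_size(px, 3)
    gx = ndimage.correlate(px, _SOBEL_X, mode="constant")
    gy = ndimage.correlate(px, _SOBEL_X.T, mode="constant")
    interior = (slice(1, -1), slice(1, -1))
    return float(np.sum(gx[interior] ** 2 + gy[interior] ** 2))


def variance(image) -> float:
    """Population variance of the intensities (mean squared deviation)."""
    return float(np.var(_as_float(image)))


def std(image) -> float:
    """Population standard deviation of the intensities."""
    return float(np.std(_as_float(image)))


def laplacian_smoothness(image, variant: str = "standard") -> float:
    """Second-derivative smoothness score psi; smaller means smoother.

    Sums, over interior pixels, the squared response
    ``f(i+1,j) + f(i-1,j) + f(i,j+1) + f(i,j-1) - k*f(i,j)`` with ``k=4``
    (``variant="standard"``, the 4-connected Laplacian, zero on constant
    images) or ``k=1`` (``variant="as_printed"``, retaining the center
    weight of the published formula, which scores a constant image at
    9c^2 per interior pixel).
    """
    px = _as_float(image)
    _require_min_size(px, 3)
    if variant == "standard":
        k = 4.0
    elif variant == "as_printed":
        k = 1.0
    else:
        raise ValueError(f"variant must be 'standard' or 'as_printed', got {variant!r}")
    core = px[1:-1, 1:-1]
    resp = px[2:, 1:-1] + px[:-2, 1:-1] + px[1:-1, 2:] + px[1:-1, :-2] - k * core
    return float(np.sum(resp**2))


def snr(image, signal_mask: Optional[np.ndarray] = None) -> float:
    """Signal-to-noise ratio in dB (package convention).

    With a signal mask: ``20*log10(mean(signal) / std(background))`` where
    the background is the mask complement.  Without a mask the whole-image
    ``20*log10(mean/std)`` is reported.  A zero denominator returns +inf
    with a warning.
    """
    px = _as_float(image)
    if signal_mask is not None:
        signal_mask = np.asarray(signal_mask, dtype=bool)
        if signal_mask.shape != px.shape:
            raise ValueError("signal_mask shape must match the image")
        if not signal_mask.any() or signal_mask.all():
            raise ValueError("signal mask and its complement must both be non-empty")
        num = float(px[signal_mask].mean())
        den = float(px[~signal_mask].std())
    else:
        num = float(px.mean())
        den = float(px.std())
    if den == 0:
        warnings.warn("zero noise spread; SNR reported as +inf", UserWarning, stacklevel=2)
        return math.inf
    return 20.0 * math.log10(num / den) if num > 0 else -math.inf


def quality_report(image, signal_mask: Optional[np.ndarray] = None, name: str = "") -> QualityReport:
    """All indicators for one image, bundled for serialization."""
    v = variance(image)
    return QualityReport(
        tenengrad=tenengrad(image),
        variance=v,
        laplace_smoothness=laplacian_smoothness(image),
        snr_db=snr(image, signal_mask),
        std=math.sqrt(v),
        name=name,
    )


_FIELDS = ["name", "tenengrad", "variance", "laplace_smoothness", "snr_db", "std"]


def write_reports_csv(reports: list[QualityReport], path) -> Path:
    """One CSV row per report; an empty batch yields a header-only file."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_FIELDS)
        writer.writeheader()
        for r in reports:
            writer.writerow({k: asdict(r)[k] for k in _FIELDS})
    return path


def write_reports_json(reports: list[QualityReport], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in reports], fh, indent=2)
    return path
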
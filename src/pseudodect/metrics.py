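"""Image-quality metrics: RMSE, PSNR, CNR, coefficient of variation, masks.

RMSE is computed over the voxels of an evaluation mask; PSNR follows
``20 log10(I_max / RMSE)`` with ``I_max`` the maximum of the display intensity
scale (HU shifted by +1024), recorded in the report.  CNR uses the sample
standard deviation of the background ROI.  The evaluation mask intersects the
phantom support with the restricted high-energy FOV disk so truncated and
untruncated images are compared over the same voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CTImage

__all__ = ["EvaluationMask", "MetricReport", "rmse_psnr", "cnr",
           "coefficient_of_variation", "make_mask"]

DEFAULT_I_MAX = 3095.0   # top of the shifted (HU + 1024) display scale
PSNR_INF = float("inf")


@dataclass
class EvaluationMask:
    mask: np.ndarray                 # boolean
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError("evaluation mask is empty")


@dataclass
class MetricReport:
    rmse_hu: float
    psnr_db: float
    i_max: float
    n_voxels: int
    cnr: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)


def rmse_psnr(real: CTImage, pseudo: CTImage, mask: EvaluationMask,
              i_max: float = DEFAULT_I_MAX) -> MetricReport:
    """RMSE (HU) and PSNR (dB) between two images over the masked voxels."""
    if real.shape != pseudo.shape:
        raise ValueError("image grids differ")
    if mask.mask.shape != real.shape:
        raise ValueError("mask grid differs from the images")
    diff = real.values[mask.mask] - pseudo.values[mask.mask]
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    psnr = PSNR_INF if rmse == 0 else float(20.0 * np.log10(i_max / rmse))
    return MetricReport(rmse, psnr, i_max, int(mask.mask.sum()))


def cnr(image: CTImage, roi_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio (ROI mean - background mean) / background SD."""
    roi_mask = np.asarray(roi_mask, bool)
    bg_mask = np.asarray(bg_mask, bool)
    if np.any(roi_mask & bg_mask):
        raise ValueError("ROI and background overlap")
    sd = float(np.std(image.values[bg_mask], ddof=1))
    if sd == 0:
        raise ZeroDivisionError("background has zero variance")
    return float((image.values[roi_mask].mean() - image.values[bg_mask].mean()) / sd)


def coefficient_of_variation(values) -> float:
    """Sample SD / mean of CT numbers across phantom sizes."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("zero mean")
    return float(np.std(v, ddof=1) / mean)


def make_mask(support: np.ndarray, fov_diameter_mm: float | None,
              spacing: float) -> EvaluationMask:
    """Voxels valid for comparison: inside the phantom support and inside the
    FOV disk (both conditions must hold)."""
    support = np.asarray(support, bool)
    if not support.any():
        raise ValueError("empty phantom support")
    mask = support.copy()
    if fov_diameter_mm is not None:
        n = support.shape[0]
        c = (np.arange(n) - (n - 1) / 2.0) * spacing
        xx, yy = np.meshgrid(c, c)
        mask &= xx ** 2 + yy ** 2 <= (fov_diameter_mm / 2.0) ** 2
    if not mask.any():
        raise ValueError("mask is empty after FOV restriction")
    return EvaluationMask(mask, {"fov_diameter_mm": fov_diameter_mm,
                                 "spacing_mm": spacing})
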
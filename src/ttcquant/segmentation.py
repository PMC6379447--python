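"""Two-stage supervised extraction of infarct and normal tissue.

Stage one binarizes brightness: pixels strictly brighter than ``t_infarct``
form the infarct mask.  Stage two extracts normal (stained) tissue from the
background: pixels whose red channel strictly exceeds ``t_red`` AND whose
hue lies in the red band ``[-60*F, +60*F]`` AND that were not already
assigned to the infarct.  The infarct ratio is reported as a percentage of
the whole section, ``100 * n_infarct / (n_infarct + n_normal)``; background
pixels inside the ROI never enter the denominator.

Thresholds are user-supervised: the canonical workflow is to pick them by
inspecting a :func:`threshold_sweep`.  :func:`suggest_thresholds` offers an
automatic (Otsu-based) starting point and is an explicit convenience
extension, not part of the supervised method itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .colorimetry import (
    F_HUE_MAX,
    ThresholdConfig,
    brightness_array,
    red_band_array,
)
from .exceptions import (
    ContractError,
    DegenerateHistogramError,
    DomainError,
    EmptySectionError,
)
from .image_io import ROI, as_rgb_array, crop_roi, save_png

__all__ = [
    "SectionResult",
    "SweepPoint",
    "infarct_mask",
    "normal_mask",
    "analyze_section",
    "threshold_sweep",
    "suggest_thresholds",
    "average_results",
    "remove_small_components",
    "save_mask",
    "save_overlay",
    "result_record",
    "RESULT_COLUMNS",
]

SWEEPABLE_PARAMETERS = ("t_infarct", "t_red", "f_hue")

RESULT_COLUMNS = [
    "section_id",
    "x0",
    "y0",
    "x1",
    "y1",
    "t_infarct",
    "t_red",
    "f_hue",
    "n_infarct",
    "n_normal",
    "ratio_percent",
]


@dataclass(frozen=True)
class SectionResult:
    """Pixel counts and infarct ratio for one analyzed section."""

    n_infarct: int
    n_normal: int
    ratio_percent: float
    config: ThresholdConfig
    roi: ROI

    @property
    def n_section(self) -> int:
        return self.n_infarct + self.n_normal


@dataclass(frozen=True)
class SweepPoint:
    """One step of a parameter sweep: the value, result, and both masks."""

    value: float
    result: SectionResult
    infarct: np.ndarray
    normal: np.ndarray


def _check_threshold(value: float, name: str) -> None:
    if not 0 <= value <= 255:
        raise DomainError(f"{name}={value!r} outside [0, 255]")


def infarct_mask(image: np.ndarray, t_infarct: float) -> np.ndarray:
    """Boolean mask of pixels with brightness strictly above ``t_infarct``."""
    image = as_rgb_array(image)
    _check_threshold(t_infarct, "t_infarct")
    return brightness_array(image) > t_infarct


def normal_mask(
    image: np.ndarray,
    t_red: float,
    f_hue: float,
    infarct: np.ndarray,
) -> np.ndarray:
    """Boolean mask of red-hued tissue not already assigned to the infarct.

    A pixel is normal tissue iff its red channel strictly exceeds
    ``t_red``, its hue lies in ``[-60*f_hue, +60*f_hue]``, and it is not in
    the infarct mask.  Achromatic pixels have no hue and never qualify.
    """
    image = as_rgb_array(image)
    _check_threshold(t_red, "t_red")
    infarct = np.asarray(infarct, dtype=bool)
    if infarct.shape != image.shape[:2]:
        raise ContractError(
            f"infarct mask shape {infarct.shape} does not match image {image.shape[:2]}"
        )
    red = image[..., 0].astype(np.float64)
    return (red > t_red) & red_band_array(image, f_hue) & ~infarct


def analyze_section(
    image: np.ndarray,
    roi: ROI,
    config: ThresholdConfig,
    min_component_size: int = 0,
) -> SectionResult:
    """Crop the ROI, run both extraction stages, and compute the ratio.

    ``min_component_size`` optionally drops connected mask components
    smaller than the given pixel count before counting.  It is OFF (0) by
    default; the published method is pure per-pixel thresholding.
    """
    patch = crop_roi(image, roi)
    inf = infarct_mask(patch, config.t_infarct)
    nor = normal_mask(patch, config.t_red, config.f_hue, inf)
    if min_component_size > 0:
        inf = remove_small_components(inf, min_component_size)
        nor = remove_small_components(nor, min_component_size)
    n_infarct = int(inf.sum())
    n_normal = int(nor.sum())
    total = n_infarct + n_normal
    if total == 0:
        raise EmptySectionError(
            "no tissue detected in ROI at thresholds "
            f"t_infarct={config.t_infarct}, t_red={config.t_red}, f_hue={config.f_hue}"
        )
    return SectionResult(
        n_infarct=n_infarct,
        n_normal=n_normal,
        ratio_percent=100.0 * n_infarct / total,
        config=config,
        roi=roi,
    )


def section_masks(
    image: np.ndarray, roi: ROI, config: ThresholdConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Return (infarct, normal) masks for the ROI without counting."""
    patch = crop_roi(image, roi)
    inf = infarct_mask(patch, config.t_infarct)
    nor = normal_mask(patch, config.t_red, config.f_hue, inf)
    return inf, nor


def threshold_sweep(
    image: np.ndarray,
    roi: ROI,
    base: ThresholdConfig,
    parameter: str,
    values: Sequence[float],
) -> list[SweepPoint]:
    """Re-analyze the section at each value of one parameter.

    Batch emulation of the interactive scrollbar: all other parameters are
    held at ``base`` and the masks are returned for visual inspection.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ContractError(
            f"unknown sweep parameter {parameter!r}; expected one of {SWEEPABLE_PARAMETERS}"
        )
    values = list(values)
    if not values:
        raise ContractError("sweep requires at least one value")
    points: list[SweepPoint] = []
    for value in values:
        config = base.replace(**{parameter: value})
        inf, nor = section_masks(image, roi, config)
        n_infarct = int(inf.sum())
        n_normal = int(nor.sum())
        total = n_infarct + n_normal
        result = SectionResult(
            n_infarct=n_infarct,
            n_normal=n_normal,
            ratio_percent=(100.0 * n_infarct / total) if total else float("nan"),
            config=config,
            roi=roi,
        )
        points.append(SweepPoint(value=value, result=result, infarct=inf, normal=nor))
    return points


def suggest_thresholds(image: np.ndarray, roi: ROI) -> ThresholdConfig:
    """Propose a starting configuration from Otsu splits (non-canonical).

    ``t_red`` is the Otsu split of the red-channel histogram (background
    vs. stained tissue).  ``t_infarct`` is the Otsu split of the brightness
    histogram restricted to a provisional tissue mask (pixels brighter than
    a whole-ROI Otsu split), separating normal from infarct within tissue.
    ``f_hue`` defaults to the widest band.  The result is a starting point
    for a supervised sweep, not a substitute for supervision.
    """
    from skimage.filters import threshold_otsu

    patch = crop_roi(image, roi)
    bright = brightness_array(patch)
    if np.unique(patch.reshape(-1, 3), axis=0).shape[0] < 2:
        raise DegenerateHistogramError("constant-intensity ROI: no threshold exists")

    red = patch[..., 0].astype(np.float64)
    try:
        t_red = float(threshold_otsu(red)) if np.ptp(red) > 0 else float(red.flat[0])
        t_back = float(threshold_otsu(bright))
        tissue = bright[bright > t_back]
        if tissue.size == 0 or np.ptp(tissue) == 0:
            t_infarct = t_back
        else:
            t_infarct = float(threshold_otsu(tissue))
    except ValueError as exc:  # constant histogram inside skimage
        raise DegenerateHistogramError(str(exc)) from exc
    t_infarct = float(np.clip(t_infarct, 0.0, 255.0))
    t_red = float(np.clip(t_red, 0.0, 255.0))
    return ThresholdConfig(t_infarct=t_infarct, t_red=t_red, f_hue=F_HUE_MAX)


def average_results(a: SectionResult, b: SectionResult) -> float:
    """Mean ratio of two analysts' results for the same section."""
    if (a.roi.width, a.roi.height) != (b.roi.width, b.roi.height):
        raise ContractError(
            "cannot average results for ROIs of different size: "
            f"{(a.roi.width, a.roi.height)} vs {(b.roi.width, b.roi.height)}"
        )
    return (a.ratio_percent + b.ratio_percent) / 2.0


def remove_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_size`` pixels."""
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


# ---------------------------------------------------------------------------
# Export helpers.

OVERLAY_INFARCT = (255, 255, 0)  # yellow
OVERLAY_NORMAL = (220, 40, 40)  # red
OVERLAY_BACKGROUND = (40, 40, 40)  # dark gray


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    save_png(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8), path)


def save_overlay(
    infarct: np.ndarray, normal: np.ndarray, path: str | Path
) -> None:
    """Write a colorized class overlay (infarct/normal/background) as PNG."""
    infarct = np.asarray(infarct, dtype=bool)
    normal = np.asarray(normal, dtype=bool)
    if infarct.shape != normal.shape:
        raise ContractError("mask shapes differ")
    out = np.empty(infarct.shape + (3,), dtype=np.uint8)
    out[...] = OVERLAY_BACKGROUND
    out[normal] = OVERLAY_NORMAL
    out[infarct] = OVERLAY_INFARCT
    save_png(out, path)


def result_record(result: SectionResult, section_id: str = "") -> dict:
    """Flatten a SectionResult into the stable CSV column schema."""
    return {
        "section_id": section_id,
        "x0": result.roi.x0,
        "y0": result.roi.y0,
        "x1": result.roi.x1,
        "y1": result.roi.y1,
        "t_infarct": result.config.t_infarct,
        "t_red": result.config.t_red,
        "f_hue": result.config.f_hue,
        "n_infarct": result.n_infarct,
        "n_normal": result.n_normal,
        "ratio_percent": result.ratio_percent,
    }
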
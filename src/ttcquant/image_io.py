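"""Reading raster images into a canonical 8-bit RGB array and cropping ROIs.

The canonical in-memory representation of an image everywhere in this
package is a ``numpy.ndarray`` of shape ``(height, width, 3)`` and dtype
``uint8``.  Coordinates are 0-based, ``(x, y) = (column, row)``, and
rectangles are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import BoundsError, ContractError, FormatError

__all__ = ["ROI", "load_image", "crop_roi", "save_png", "as_rgb_array"]


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region of interest, ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def validate(self, image_width: int, image_height: int) -> None:
        """Raise :class:`BoundsError` unless the ROI is non-empty and in-bounds."""
        if self.x0 >= self.x1 or self.y0 >= self.y1:
            raise BoundsError(
                f"empty ROI: x0={self.x0} x1={self.x1} y0={self.y0} y1={self.y1}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise BoundsError(f"negative ROI origin: ({self.x0}, {self.y0})")
        if self.x1 > image_width:
            raise BoundsError(f"ROI x1={self.x1} exceeds image width {image_width}")
        if self.y1 > image_height:
            raise BoundsError(f"ROI y1={self.y1} exceeds image height {image_height}")


def as_rgb_array(pixels: np.ndarray) -> np.ndarray:
    """Validate and return ``pixels`` as an (H, W, 3) uint8 array."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ContractError(f"expected (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ContractError(f"image must be at least 1x1, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ContractError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG/TIFF file as an (H, W, 3) uint8 RGB array.

    Grayscale images are replicated across channels, alpha channels are
    discarded, and 16-bit samples are rescaled to [0, 255].  EXIF
    orientation, when present, is applied by the reader.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        import imageio.v3 as iio

        arr = iio.imread(path)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - reader errors vary by plugin
        raise FormatError(f"could not read image file {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = np.stack([arr[..., 0]] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")

    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
        else:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
    return as_rgb_array(arr)


def crop_roi(image: np.ndarray, roi: ROI) -> np.ndarray:
    """Return the sub-image covered by the half-open rectangle ``roi``."""
    image = as_rgb_array(image)
    height, width = image.shape[:2]
    roi.validate(width, height)
    return image[roi.y0 : roi.y1, roi.x0 : roi.x1, :]


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB (H, W, 3) or mask (H, W) uint8 array as a PNG file.

    PNG is lossless and the encoder settings are deterministic, so repeated
    saves of the same array are bit-identical.
    """
    import imageio.v3 as iio

    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr, extension=".png")
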
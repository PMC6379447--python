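"""Per-pixel quantities the thresholds operate on.

Three quantities drive the segmentation: brightness (arithmetic channel
mean), the raw red channel, and hue measured relative to pure red.  Hue
follows the standard HSV hexcone, recentred so that pure red sits at 0 and
angles are signed in ``(-180, +180]``.  Achromatic pixels (r = g = b) have
no hue; they are represented as ``None`` (scalar API) or NaN (array API)
and always fail the red band test.

The red band accepted by the "digital red filter" is ``[-60*F, +60*F]``
degrees for a factor ``F`` in ``[0, 0.2]``, i.e. at most ``[-12, +12]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = [
    "ThresholdConfig",
    "brightness",
    "hue_degrees",
    "in_red_band",
    "brightness_array",
    "hue_degrees_array",
    "red_band_array",
    "HUE_SPAN_PER_UNIT_F",
    "F_HUE_MAX",
]

#: Half-band width per unit of the hue factor F, in degrees.
HUE_SPAN_PER_UNIT_F = 60.0
#: Upper end of the hue factor domain.
F_HUE_MAX = 0.2


def _check_channel(value: float, name: str) -> None:
    if not 0 <= value <= 255:
        raise DomainError(f"channel {name}={value!r} outside [0, 255]")


def _check_f_hue(f_hue: float) -> None:
    if not 0.0 <= f_hue <= F_HUE_MAX:
        raise DomainError(f"hue factor {f_hue!r} outside [0, {F_HUE_MAX}]")


@dataclass(frozen=True)
class ThresholdConfig:
    """The three tuning parameters of the segmentation.

    ``t_infarct`` is the brightness threshold separating the pale infarct
    from everything darker; ``t_red`` is the red-channel threshold
    separating stained tissue from the dark background; ``f_hue`` is the
    red-filter factor F with accepted hue band ``[-60*F, +60*F]``.
    """

    t_infarct: float
    t_red: float
    f_hue: float = F_HUE_MAX

    def __post_init__(self) -> None:
        _check_channel(self.t_infarct, "t_infarct")
        _check_channel(self.t_red, "t_red")
        _check_f_hue(self.f_hue)

    def replace(self, **kwargs: float) -> "ThresholdConfig":
        fields = {"t_infarct": self.t_infarct, "t_red": self.t_red, "f_hue": self.f_hue}
        fields.update(kwargs)
        return ThresholdConfig(**fields)


def brightness(r: float, g: float, b: float) -> float:
    """Arithmetic mean of the three channels, in [0, 255].

    The mean (not the max) preserves the ordering pale infarct > deep-red
    normal tissue > dark background that the brightness binarization relies
    on; under the max, pure red would be as bright as white.
    """
    _check_channel(r, "r")
    _check_channel(g, "g")
    _check_channel(b, "b")
    return (r + g + b) / 3.0


def hue_degrees(r: float, g: float, b: float) -> float | None:
    """Signed HSV hue in ``(-180, +180]`` with pure red at 0.

    Returns ``None`` for achromatic pixels (r = g = b).
    """
    _check_channel(r, "r")
    _check_channel(g, "g")
    _check_channel(b, "b")
    mx = max(r, g, b)
    mn = min(r, g, b)
    delta = mx - mn
    if delta == 0:
        return None
    if mx == r:
        h = 60.0 * (((g - b) / delta) % 6.0)
    elif mx == g:
        h = 60.0 * ((b - r) / delta + 2.0)
    else:
        h = 60.0 * ((r - g) / delta + 4.0)
    if h > 180.0:
        h -= 360.0
    return h


def in_red_band(h: float | None, f_hue: float) -> bool:
    """True iff hue ``h`` is defined and lies in ``[-60*F, +60*F]``."""
    _check_f_hue(f_hue)
    if h is None:
        return False
    half_band = HUE_SPAN_PER_UNIT_F * f_hue
    return -half_band <= h <= half_band


# ---------------------------------------------------------------------------
# Vectorized forms operating on (H, W, 3) uint8 arrays.

def brightness_array(image: np.ndarray) -> np.ndarray:
    """Per-pixel brightness of an (H, W, 3) array as float64 (H, W)."""
    arr = np.asarray(image, dtype=np.float64)
    return arr[..., :3].sum(axis=-1) / 3.0


def hue_degrees_array(image: np.ndarray) -> np.ndarray:
    """Per-pixel signed hue in ``(-180, +180]``; NaN where achromatic."""
    arr = np.asarray(image, dtype=np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = np.max(arr[..., :3], axis=-1)
    mn = np.min(arr[..., :3], axis=-1)
    delta = mx - mn
    chromatic = delta > 0
    safe = np.where(chromatic, delta, 1.0)

    h = np.empty(mx.shape, dtype=np.float64)
    is_r = (mx == r) & chromatic
    is_g = (mx == g) & chromatic & ~is_r
    is_b = chromatic & ~is_r & ~is_g
    h[is_r] = 60.0 * (((g - b)[is_r] / safe[is_r]) % 6.0)
    h[is_g] = 60.0 * ((b - r)[is_g] / safe[is_g] + 2.0)
    h[is_b] = 60.0 * ((r - g)[is_b] / safe[is_b] + 4.0)
    h[h > 180.0] -= 360.0
    h[~chromatic] = np.nan
    return h


def red_band_array(image: np.ndarray, f_hue: float) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose hue lies in the red band."""
    _check_f_hue(f_hue)
    h = hue_degrees_array(image)
    half_band = HUE_SPAN_PER_UNIT_F * f_hue
    with np.errstate(invalid="ignore"):
        return (h >= -half_band) & (h <= half_band)
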
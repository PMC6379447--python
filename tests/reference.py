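"""Naive per-pixel reference implementations used as test oracles.

These deliberately avoid the vectorized code paths under test: masks are
built with plain Python loops over pixels, applying the published
conditions one pixel at a time via the scalar colorimetry functions.
"""

from __future__ import annotations

import numpy as np

from ttcquant.colorimetry import brightness, hue_degrees, in_red_band


def ref_infarct_mask(image: np.ndarray, t_infarct: float) -> np.ndarray:
    h, w = image.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            r, g, b = (int(c) for c in image[y, x])
            mask[y, x] = brightness(r, g, b) > t_infarct
    return mask


def ref_normal_mask(
    image: np.ndarray, t_red: float, f_hue: float, infarct: np.ndarray
) -> np.ndarray:
    h, w = image.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if infarct[y, x]:
                continue
            r, g, b = (int(c) for c in image[y, x])
            mask[y, x] = r > t_red and in_red_band(hue_degrees(r, g, b), f_hue)
    return mask


def ref_otsu(values: np.ndarray) -> float:
    """Exhaustive Otsu criterion over integer cut points 0..254.

    Returns the cut t maximizing the between-class variance of the split
    ``values <= t`` vs ``values > t``.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    best_t, best_var = 0.0, -1.0
    for t in range(255):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, float(t)
    return best_t
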
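"""Seeded synthetic section photographs with pixel-level ground truth.

No image dataset accompanies the method, so tests and simulations run on
generated fixtures that emulate its assumptions: a near-black background
plate, an elliptical section of deep-red (hue ~ 0) normal tissue with a
pale high-brightness infarct sub-region, and optional non-red impurity
blobs.  Every pixel carries a ground-truth class label, so recovered
ratios can be checked against exact integer pixel arithmetic.

Generation is deterministic given the seed; there is no unseeded path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .colorimetry import brightness
from .exceptions import ContractError
from .image_io import ROI

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_NORMAL",
    "LABEL_INFARCT",
    "LABEL_IMPURITY",
    "Palette",
    "EllipseSpec",
    "FixtureParams",
    "GroundTruth",
    "AnimalFixture",
    "generate_section",
    "generate_study",
    "full_roi",
    "mid_gap_config",
]

LABEL_BACKGROUND = 0
LABEL_NORMAL = 1
LABEL_INFARCT = 2
LABEL_IMPURITY = 3

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class Palette:
    """Noiseless class colors.

    Defaults: near-black plate, deep-red normal tissue (hue exactly 0),
    pale slightly warm infarct.  Construction asserts the orderings the
    segmentation relies on: brightness(infarct) > brightness(normal) >
    brightness(background), and red(normal) > red(background).
    """

    background: RGB = (8, 8, 8)
    normal: RGB = (170, 30, 30)
    infarct: RGB = (230, 225, 215)

    def __post_init__(self) -> None:
        b_bg = brightness(*self.background)
        b_no = brightness(*self.normal)
        b_in = brightness(*self.infarct)
        if not (b_in > b_no > b_bg):
            raise ContractError(
                "palette must satisfy brightness(infarct) > brightness(normal) "
                f"> brightness(background); got {b_in:.1f}, {b_no:.1f}, {b_bg:.1f}"
            )
        if not self.normal[0] > self.background[0]:
            raise ContractError("palette must satisfy red(normal) > red(background)")


@dataclass(frozen=True)
class EllipseSpec:
    """Axis-aligned ellipse: center (cx, cy) and semi-axes (a, b), in pixels."""

    cx: float
    cy: float
    a: float
    b: float

    def mask(self, width: int, height: int) -> np.ndarray:
        y, x = np.mgrid[0:height, 0:width]
        return ((x - self.cx) / self.a) ** 2 + ((y - self.cy) / self.b) ** 2 <= 1.0

    def within(self, width: int, height: int) -> bool:
        return (
            self.cx - self.a >= 0
            and self.cx + self.a <= width - 1
            and self.cy - self.b >= 0
            and self.cy + self.b <= height - 1
        )


@dataclass(frozen=True)
class FixtureParams:
    """Everything needed to render one synthetic section deterministically.

    ``infarct`` is either an :class:`EllipseSpec` inside the section, a
    float in [0, 100] requesting a half-plane-style cut covering that
    percentage of the section's pixels (the nearest achievable integer
    pixel count is used), or ``None`` for a section with no infarct.
    """

    width: int = 160
    height: int = 120
    section: EllipseSpec = field(default_factory=lambda: EllipseSpec(80, 60, 55, 40))
    infarct: EllipseSpec | float | None = 30.0
    palette: Palette = field(default_factory=Palette)
    noise_sd: float = 0.0
    impurities: tuple[tuple[EllipseSpec, RGB], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ContractError("image must be at least 1x1")
        if not self.section.within(self.width, self.height):
            raise ContractError("section ellipse extends outside the image")
        if isinstance(self.infarct, (int, float)) and not isinstance(self.infarct, bool):
            if not 0.0 <= float(self.infarct) <= 100.0:
                raise ContractError(f"infarct percentage {self.infarct} outside [0, 100]")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be non-negative")
        for blob, _color in self.impurities:
            if not blob.within(self.width, self.height):
                raise ContractError("impurity blob extends outside the image")


@dataclass(frozen=True)
class GroundTruth:
    """Per-pixel class labels plus the exact infarct fraction."""

    labels: np.ndarray  # (H, W) uint8 with LABEL_* values

    @property
    def n_infarct(self) -> int:
        return int((self.labels == LABEL_INFARCT).sum())

    @property
    def n_normal(self) -> int:
        return int((self.labels == LABEL_NORMAL).sum())

    @property
    def true_fraction(self) -> float:
        """``100 * |infarct| / (|infarct| + |normal|)`` from the label map."""
        total = self.n_infarct + self.n_normal
        if total == 0:
            raise ContractError("ground truth contains no tissue pixels")
        return 100.0 * self.n_infarct / total


def _infarct_labels(params: FixtureParams, section: np.ndarray) -> np.ndarray:
    """Boolean infarct mask within the section, honoring the infarct spec."""
    if params.infarct is None:
        return np.zeros_like(section)
    if isinstance(params.infarct, EllipseSpec):
        inf = params.infarct.mask(params.width, params.height)
        if np.any(inf & ~section):
            raise ContractError("infarct ellipse is not contained in the section")
        return inf
    # Percentage spec: fill the requested share of section pixels from the
    # left (a cut through the section), using the nearest integer count.
    pct = float(params.infarct)
    ys, xs = np.nonzero(section)
    order = np.lexsort((ys, xs))  # sort by column, then row
    k = int(round(pct / 100.0 * xs.size))
    inf = np.zeros_like(section)
    inf[ys[order[:k]], xs[order[:k]]] = True
    return inf


def generate_section(params: FixtureParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one section image and its ground-truth label map.

    Pixels receive their class color plus i.i.d. per-channel Gaussian noise
    (sd = ``params.noise_sd``), rounded and clipped to [0, 255].  The label
    map records the noiseless classes.  Impurity blobs are painted over
    background only, so adding them never changes the tissue ground truth.
    """
    section = params.section.mask(params.width, params.height)
    infarct = _infarct_labels(params, section)

    labels = np.full((params.height, params.width), LABEL_BACKGROUND, dtype=np.uint8)
    labels[section] = LABEL_NORMAL
    labels[infarct] = LABEL_INFARCT

    image = np.empty((params.height, params.width, 3), dtype=np.float64)
    image[...] = params.palette.background
    image[labels == LABEL_NORMAL] = params.palette.normal
    image[labels == LABEL_INFARCT] = params.palette.infarct
    for blob, color in params.impurities:
        spot = blob.mask(params.width, params.height) & (labels == LABEL_BACKGROUND)
        labels[spot] = LABEL_IMPURITY
        image[spot] = color

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return image, GroundTruth(labels=labels)


@dataclass(frozen=True)
class AnimalFixture:
    """One study animal: rendered image, truth, and provenance."""

    animal_id: str
    image: np.ndarray
    truth: GroundTruth
    params: FixtureParams
    requested_fraction: float

    def manifest_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "seed": self.params.seed,
            "noise_sd": self.params.noise_sd,
            "requested_fraction": self.requested_fraction,
            "true_fraction": self.truth.true_fraction,
        }


def generate_study(
    n_animals: int,
    fraction_range: tuple[float, float],
    template: FixtureParams | None = None,
    seed: int = 0,
) -> list[AnimalFixture]:
    """Generate a seeded study of sections with fractions drawn uniformly.

    Each animal gets an independent child seed; its target fraction is
    drawn uniformly in ``fraction_range`` and realized via the percentage
    infarct spec (so the achieved per-pixel fraction is the nearest integer
    pixel count, recorded in the manifest).
    """
    if n_animals < 2:
        raise ContractError("a study requires at least 2 animals")
    lo, hi = fraction_range
    if not (0.0 <= lo <= hi <= 100.0):
        raise ContractError(f"invalid fraction range [{lo}, {hi}]")
    template = template or FixtureParams()
    ss = np.random.SeedSequence(seed)
    frac_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(n_animals, dtype=np.uint32)

    fixtures: list[AnimalFixture] = []
    for i in range(n_animals):
        target = float(frac_rng.uniform(lo, hi))
        params = replace(template, infarct=target, seed=int(child_seeds[i]))
        image, truth = generate_section(params)
        fixtures.append(
            AnimalFixture(
                animal_id=f"animal{i + 1:02d}",
                image=image,
                truth=truth,
                params=params,
                requested_fraction=target,
            )
        )
    return fixtures


def full_roi(params: FixtureParams) -> ROI:
    """ROI covering the whole fixture image."""
    return ROI(0, 0, params.width, params.height)


def mid_gap_config(palette: Palette | None = None) -> "ThresholdConfig":
    """Thresholds centred in the gaps between the palette's class levels.

    ``t_infarct`` is halfway between the normal and infarct brightness
    levels; ``t_red`` halfway between the background and normal red
    channels; ``f_hue`` at the widest band.
    """
    from .colorimetry import F_HUE_MAX, ThresholdConfig

    palette = palette or Palette()
    b_normal = brightness(*palette.normal)
    b_infarct = brightness(*palette.infarct)
    return ThresholdConfig(
        t_infarct=(b_normal + b_infarct) / 2.0,
        t_red=(palette.background[0] + palette.normal[0]) / 2.0,
        f_hue=F_HUE_MAX,
    )
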
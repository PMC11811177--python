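"""Synthetic chest-radiograph phantoms with ground-truth lung masks.

Generates deterministic 8-bit grayscale images that mimic the gross
structure of a portable supine chest radiograph: two bright elliptical
lung fields on a darker thorax, periodic rib-like bands, optional
low-contrast lesion blobs, and additive per-pixel noise.  Every phantom
ships with its exact lung mask and lesion map, so downstream modules can
be tested without any clinical data.

Coordinate convention: (row, col), top-left origin, 0-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from boclahe.errors import ArgumentError, ConfigurationError

__all__ = ["PhantomSpec", "generate_phantom", "phantom_batch", "item_seed"]

#: default lung ellipses as (center_row_frac, center_col_frac,
#: semi_axis_row_frac, semi_axis_col_frac)
_DEFAULT_LUNGS = (
    (0.45, 0.30, 0.30, 0.17),
    (0.45, 0.70, 0.30, 0.17),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic chest phantom.

    All intensities are on the 8-bit scale.  Lesions are
    ``(center_row, center_col, radius_px, contrast_delta)`` tuples;
    the delta is added to pixels of the lesion disc that fall inside
    the lung mask.
    """

    width: int = 160
    height: int = 160
    background_level: float = 30.0
    lung_fill: float = 120.0
    lung_ellipses: tuple = _DEFAULT_LUNGS
    rib_count: int = 4
    rib_amplitude: float = 12.0
    lesions: tuple = ()
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 32:
            raise ConfigurationError("width must be >= 32")
        if self.height < 32:
            raise ConfigurationError("height must be >= 32")
        for name in ("background_level", "lung_fill"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ConfigurationError(f"{name} must be in [0, 255]")
        if len(self.lung_ellipses) != 2:
            raise ConfigurationError("lung_ellipses must hold exactly two ellipses")
        for ell in self.lung_ellipses:
            if len(ell) != 4 or not all(0.0 < f < 1.0 for f in ell):
                raise ConfigurationError(
                    "lung_ellipses entries must be four fractions in (0, 1)"
                )
        if self.rib_count < 0:
            raise ConfigurationError("rib_count must be >= 0")
        for les in self.lesions:
            if len(les) != 4:
                raise ConfigurationError("lesions entries must be 4-tuples")
            r, c, rad, _ = les
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ConfigurationError("lesions center outside image bounds")
            if rad <= 0:
                raise ConfigurationError("lesions radius must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        object.__setattr__(self, "lung_ellipses", tuple(tuple(e) for e in self.lung_ellipses))
        object.__setattr__(self, "lesions", tuple(tuple(l) for l in self.lesions))

    def to_json(self) -> str:
        """Serialize as a flat JSON document."""
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        return cls(**d)


def _lung_mask(spec: PhantomSpec) -> np.ndarray:
    rows = np.arange(spec.height, dtype=float)[:, None]
    cols = np.arange(spec.width, dtype=float)[None, :]
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for cr, cc, ar, ac in spec.lung_ellipses:
        cy = cr * spec.height
        cx = cc * spec.width
        ay = ar * spec.height
        ax = ac * spec.width
        mask |= ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0
    return mask


def generate_phantom(spec: PhantomSpec, seed=None):
    """Render one phantom.

    Returns ``(image, mask, lesion_map)``: a uint8 image, the boolean
    lung mask, and the boolean lesion map (lesion discs intersected with
    the lung mask).  The output is a pure function of ``(spec, seed)``;
    ``seed=None`` falls back to ``spec.seed``.
    """
    if seed is None:
        seed = spec.seed
    mask = _lung_mask(spec)

    img = np.full((spec.height, spec.width), float(spec.background_level))
    img[mask] = spec.lung_fill

    if spec.rib_count > 0 and spec.rib_amplitude != 0:
        rows = np.arange(spec.height, dtype=float)
        rib = spec.rib_amplitude * np.sin(2.0 * np.pi * spec.rib_count * rows / spec.height)
        img += np.where(mask, rib[:, None], 0.0)

    lesion_map = np.zeros_like(mask)
    if spec.lesions:
        rr = np.arange(spec.height, dtype=float)[:, None]
        cc = np.arange(spec.width, dtype=float)[None, :]
        for lr, lc, rad, delta in spec.lesions:
            disc = (rr - lr) ** 2 + (cc - lc) ** 2 <= rad**2
            disc &= mask
            img[disc] += delta
            lesion_map |= disc

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, mask, lesion_map


def item_seed(seed: int, i: int) -> int:
    """Stable per-item seed so batch item *i* can be regenerated alone."""
    return int(np.random.SeedSequence([int(seed), int(i)]).generate_state(1)[0])


def phantom_batch(spec: PhantomSpec, n: int, seed: int):
    """Generate ``n`` phantom triples; item *i* depends only on (spec, seed, i)."""
    if n < 1:
        raise ArgumentError("n must be >= 1")
    return [generate_phantom(spec, item_seed(seed, i)) for i in range(n)]
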
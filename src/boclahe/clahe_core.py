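"""From-scratch CLAHE on 8-bit grayscale images.

The image is divided into an ``g x g`` grid of tiles (uneven tiles when
the image size is not divisible by ``g``; the last row/column of tiles
absorbs the remainder).  Each tile's 256-bin histogram is clipped at a
ceiling proportional to the clip limit, the clipped excess is
redistributed deterministically, and an equalization lookup table is
built per tile.  Output pixels are the bilinear blend of the four
surrounding tile mappings, with clamped replication outside the lattice
of tile centers.

Conventions that affect bit-exact comparisons:

* rounding is round-half-up everywhere (``floor(x + 0.5)``);
* clip ceiling per tile: ``max(1, round(clip_limit * tile_pixels / 256))``;
* redistribution: truncate, pool the excess, add ``excess // 256`` to
  every bin, then deposit the remainder one count at a time starting
  from bin 0;
* LUT: ``round(255 * (cdf(v) - cdf_min) / (n_pixels - cdf_min))`` with
  ``cdf_min`` the first nonzero cumulative value; a single-bin histogram
  maps to the identity;
* tile centers sit at ``(start + end - 1) / 2`` in pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from boclahe.errors import ArgumentError, ConsistencyError, SizeError

__all__ = [
    "ClaheParams",
    "compute_histogram",
    "clip_and_redistribute",
    "build_tile_lut",
    "clahe",
    "apply_clahe_masked",
]


@dataclass(frozen=True)
class ClaheParams:
    """The optimized CLAHE parameter pair.

    ``clip_limit`` is the histogram-height ceiling as a multiple of the
    uniform bin height; ``tile_grid`` is the (real-valued) number of
    tiles per axis, rounded to ``effective_grid`` before use.  The
    optimizer searches ``clip_limit`` in [1, 255] and ``tile_grid`` in
    [8, 32]; the type itself additionally admits ``tile_grid >= 1`` so
    degenerate configurations (single tile = global equalization) can be
    expressed.
    """

    clip_limit: float
    tile_grid: float

    def __post_init__(self):
        if not (1.0 <= self.clip_limit <= 255.0):
            raise ArgumentError("clip_limit must be in [1.0, 255.0]")
        if not (1.0 <= self.tile_grid <= 256.0):
            raise ArgumentError("tile_grid must be in [1.0, 256.0]")

    @property
    def effective_grid(self) -> int:
        return max(1, _round_half_up_scalar(self.tile_grid))


def _round_half_up_scalar(x: float) -> int:
    return int(np.floor(x + 0.5))


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5)


def _as_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ArgumentError("image must be a nonempty 2D array")
    if img.dtype != np.uint8:
        if np.any((img < 0) | (img > 255)):
            raise ArgumentError("image values must be in [0, 255]")
        img = img.astype(np.uint8)
    return img


def compute_histogram(region) -> np.ndarray:
    """256-bin intensity histogram of a region; bins sum to the pixel count."""
    img = _as_image(region)
    return np.bincount(img.ravel(), minlength=256).astype(np.int64)


def clip_and_redistribute(hist, clip_count: int) -> np.ndarray:
    """Clip every bin to ``clip_count`` and redistribute the excess.

    Total count is preserved: after truncation the pooled excess is
    spread as ``excess // 256`` to every bin, and the remaining
    ``excess % 256`` counts are deposited one each into bins 0, 1, ...
    """
    hist = np.asarray(hist, dtype=np.int64)
    if hist.shape != (256,):
        raise ArgumentError("hist must have 256 bins")
    if np.any(hist < 0):
        raise ArgumentError("histogram bins must be non-negative")
    clip_count = int(clip_count)
    if clip_count < 1:
        raise ArgumentError("clip_count must be >= 1")
    clipped = np.minimum(hist, clip_count)
    excess = int((hist - clipped).sum())
    out = clipped + excess // 256
    rem = excess % 256
    out[:rem] += 1
    return out


def build_tile_lut(hist, n_pixels: int) -> np.ndarray:
    """Equalization lookup table from a tile histogram.

    ``mapping(v) = round(255 * (cdf(v) - cdf_min) / (n_pixels - cdf_min))``
    where ``cdf_min`` is the first nonzero cumulative value.  A histogram
    with all mass in one bin maps to the identity, so constant tiles are
    left untouched.
    """
    hist = np.asarray(hist, dtype=np.int64)
    if hist.shape != (256,):
        raise ArgumentError("hist must have 256 bins")
    n_pixels = int(n_pixels)
    if n_pixels <= 0 or int(hist.sum()) != n_pixels:
        raise ConsistencyError("n_pixels must equal the histogram total")
    cdf = np.cumsum(hist)
    cdf_min = int(cdf[cdf > 0][0])
    denom = n_pixels - cdf_min
    if denom == 0:
        return np.arange(256, dtype=np.uint8)
    lut = _round_half_up(255.0 * (cdf - cdf_min) / denom)
    return np.clip(lut, 0, 255).astype(np.uint8)


def _tile_edges(n: int, g: int) -> np.ndarray:
    """Tile boundaries along one axis; the last tile absorbs the remainder."""
    base = n // g
    edges = np.arange(g + 1, dtype=np.int64) * base
    edges[g] = n
    return edges


def _axis_interp(n: int, edges: np.ndarray):
    """Per-pixel (lower tile index, blend weight) along one axis.

    Pixels at or beyond the outermost tile centers use the clamped
    nearest mapping (weight 0 toward a duplicated neighbor).
    """
    g = len(edges) - 1
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    coords = np.arange(n, dtype=float)
    lo = np.searchsorted(centers, coords, side="right") - 1
    lo = np.clip(lo, 0, g - 1)
    hi = np.minimum(lo + 1, g - 1)
    span = centers[hi] - centers[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(span > 0, (coords - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)
    return lo, hi, w


def _tile_luts(img: np.ndarray, params: ClaheParams) -> np.ndarray:
    g = params.effective_grid
    rows, cols = img.shape
    re = _tile_edges(rows, g)
    ce = _tile_edges(cols, g)
    luts = np.empty((g, g, 256), dtype=np.uint8)
    for i in range(g):
        for j in range(g):
            tile = img[re[i]:re[i + 1], ce[j]:ce[j + 1]]
            n_pix = tile.size
            hist = compute_histogram(tile)
            if np.count_nonzero(hist) == 1:
                # constant tile: identity, never redistributed to a ramp
                luts[i, j] = np.arange(256, dtype=np.uint8)
                continue
            clip_count = max(1, _round_half_up_scalar(params.clip_limit * n_pix / 256.0))
            hist = clip_and_redistribute(hist, clip_count)
            luts[i, j] = build_tile_lut(hist, n_pix)
    return luts


def clahe(image, params: ClaheParams) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a full image."""
    img = _as_image(image)
    g = params.effective_grid
    rows, cols = img.shape
    if rows < g or cols < g:
        raise SizeError(
            f"image ({rows}x{cols}) smaller than effective grid {g} in some axis"
        )
    luts = _tile_luts(img, params)
    re = _tile_edges(rows, g)
    ce = _tile_edges(cols, g)
    rlo, rhi, wr = _axis_interp(rows, re)
    clo, chi, wc = _axis_interp(cols, ce)

    v = img  # (rows, cols) uint8 used as the LUT index
    t00 = luts[rlo[:, None], clo[None, :], v].astype(float)
    t01 = luts[rlo[:, None], chi[None, :], v].astype(float)
    t10 = luts[rhi[:, None], clo[None, :], v].astype(float)
    t11 = luts[rhi[:, None], chi[None, :], v].astype(float)
    wr2 = wr[:, None]
    wc2 = wc[None, :]
    blend = (
        (1 - wr2) * (1 - wc2) * t00
        + (1 - wr2) * wc2 * t01
        + wr2 * (1 - wc2) * t10
        + wr2 * wc2 * t11
    )
    return np.clip(_round_half_up(blend), 0, 255).astype(np.uint8)


def apply_clahe_masked(image, mask, params: ClaheParams) -> np.ndarray:
    """Apply CLAHE inside a mask, leaving outside pixels bit-identical.

    CLAHE is computed on the tight bounding box of the mask; enhanced
    values are composited back through the mask.  An all-false mask
    returns the input unchanged (callers report the warning).
    """
    img = _as_image(image)
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise ConsistencyError("mask shape must match image shape")
    if not m.any():
        return img.copy()
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = img[r0:r1, c0:c1]
    enhanced = clahe(crop, params)
    out = img.copy()
    sub = out[r0:r1, c0:c1]
    sub[m[r0:r1, c0:c1]] = enhanced[m[r0:r1, c0:c1]]
    return out
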
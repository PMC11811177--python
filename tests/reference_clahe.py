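"""A second, independently written CLAHE implementation.

Shares the documented conventions (round-half-up, two-phase excess
redistribution, cdf-min LUT, remainder-absorbing tiles, clamped border
replication) but takes a different computational route: fractional tile
coordinates via np.interp and per-neighbor gather loops instead of
searchsorted index arrays, histograms via np.histogram.

Used by the acceptance suite as the cross-implementation reference in
place of OpenCV, which is not available in the offline test image.
"""

from __future__ import annotations

import numpy as np


def _clip_redistribute(hist: np.ndarray, ceiling: int) -> np.ndarray:
    over = hist - ceiling
    over[over < 0] = 0
    pooled = int(over.sum())
    h = np.where(hist > ceiling, ceiling, hist) + pooled // 256
    h[: pooled % 256] += 1
    return h


def _equalize_lut(hist: np.ndarray, total: int) -> np.ndarray:
    cum = hist.cumsum()
    first = cum[np.nonzero(cum)[0][0]]
    if total == first:
        return np.arange(256)
    scaled = 255.0 * (cum - first) / (total - first)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.int64)


def reference_clahe(image: np.ndarray, clip_limit: float, tile_grid: float) -> np.ndarray:
    img = np.asarray(image, dtype=np.int64)
    rows, cols = img.shape
    g = int(np.floor(tile_grid + 0.5))
    g = max(g, 1)

    r_edges = np.r_[np.arange(g) * (rows // g), rows]
    c_edges = np.r_[np.arange(g) * (cols // g), cols]

    luts = np.zeros((g, g, 256), dtype=np.int64)
    for ti in range(g):
        for tj in range(g):
            tile = img[r_edges[ti]:r_edges[ti + 1], c_edges[tj]:c_edges[tj + 1]]
            hist, _ = np.histogram(tile, bins=256, range=(-0.5, 255.5))
            if (hist > 0).sum() == 1:  # constant tile -> identity
                luts[ti, tj] = np.arange(256)
                continue
            ceiling = max(1, int(np.floor(clip_limit * tile.size / 256.0 + 0.5)))
            luts[ti, tj] = _equalize_lut(_clip_redistribute(hist, ceiling), tile.size)

    r_centers = (r_edges[:-1] + r_edges[1:] - 1) / 2.0
    c_centers = (c_edges[:-1] + c_edges[1:] - 1) / 2.0

    # fractional tile coordinate per pixel position; np.interp clamps ends
    fr = np.interp(np.arange(rows), r_centers, np.arange(g, dtype=float))
    fc = np.interp(np.arange(cols), c_centers, np.arange(g, dtype=float))
    r0 = np.minimum(np.floor(fr).astype(int), g - 1)
    c0 = np.minimum(np.floor(fc).astype(int), g - 1)
    wr = fr - r0
    wc = fc - c0
    r1 = np.minimum(r0 + 1, g - 1)
    c1 = np.minimum(c0 + 1, g - 1)

    acc = np.zeros((rows, cols))
    for ri, rw in ((r0, 1.0 - wr), (r1, wr)):
        for ci, cw in ((c0, 1.0 - wc), (c1, wc)):
            vals = luts[ri[:, None], ci[None, :], img]
            acc += rw[:, None] * cw[None, :] * vals
    return np.clip(np.floor(acc + 0.5), 0, 255).astype(np.uint8)
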
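"""Independent oracles used by the test suite.

Everything here is written against the documented conventions but
deliberately avoids calling the implementation paths it checks:
histograms via np.bincount, per-pixel Python loops for CLAHE, explicit
window extraction for SSIM, matrix-inverse GP formulas, quadrature EI.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import norm


def redistribute_oracle(hist, clip_count):
    """Step-by-step simulation of the two-phase clip/redistribute rule."""
    hist = list(int(h) for h in hist)
    excess = 0
    for i in range(256):
        if hist[i] > clip_count:
            excess += hist[i] - clip_count
            hist[i] = clip_count
    per_bin = excess // 256
    for i in range(256):
        hist[i] += per_bin
    remainder = excess - per_bin * 256
    i = 0
    while remainder > 0:
        hist[i] += 1
        remainder -= 1
        i += 1
    return np.asarray(hist, dtype=np.int64)


def _lut_from_hist(hist, n_pixels):
    cdf = np.cumsum(hist)
    cdf_min = cdf[cdf > 0][0]
    denom = n_pixels - cdf_min
    if denom == 0:
        return list(range(256))
    return [
        int(min(255, max(0, np.floor(255.0 * (cdf[v] - cdf_min) / denom + 0.5))))
        for v in range(256)
    ]


def global_he_oracle(image):
    """Plain global histogram equalization with the repo's LUT formula."""
    img = np.asarray(image, dtype=np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    lut = np.asarray(_lut_from_hist(hist, img.size), dtype=np.uint8)
    return lut[img]


def clahe_oracle(image, clip_limit, tile_grid):
    """Brute-force per-pixel CLAHE following the documented conventions."""
    img = np.asarray(image, dtype=np.uint8)
    rows, cols = img.shape
    g = max(1, int(np.floor(tile_grid + 0.5)))
    assert rows >= g and cols >= g

    def edges(n):
        base = n // g
        e = [i * base for i in range(g)] + [n]
        return e

    re, ce = edges(rows), edges(cols)
    luts = {}
    for i in range(g):
        for j in range(g):
            tile = img[re[i]:re[i + 1], ce[j]:ce[j + 1]]
            n_pix = tile.size
            hist = np.bincount(tile.ravel(), minlength=256)
            if np.count_nonzero(hist) == 1:  # constant tile -> identity
                luts[(i, j)] = list(range(256))
                continue
            clip_count = max(1, int(np.floor(clip_limit * n_pix / 256.0 + 0.5)))
            hist = redistribute_oracle(hist, clip_count)
            luts[(i, j)] = _lut_from_hist(hist, n_pix)

    rc = [(re[i] + re[i + 1] - 1) / 2.0 for i in range(g)]
    cc = [(ce[j] + ce[j + 1] - 1) / 2.0 for j in range(g)]

    def bracket(coord, centers):
        if coord <= centers[0]:
            return 0, 0, 0.0
        if coord >= centers[-1]:
            return g - 1, g - 1, 0.0
        for i in range(g - 1):
            if centers[i] <= coord <= centers[i + 1]:
                w = (coord - centers[i]) / (centers[i + 1] - centers[i])
                return i, i + 1, w
        raise AssertionError("unreachable")

    out = np.empty_like(img)
    for r in range(rows):
        ri, rj, wr = bracket(r, rc)
        for c in range(cols):
            ci, cj, wc = bracket(c, cc)
            v = img[r, c]
            blend = (
                (1 - wr) * (1 - wc) * luts[(ri, ci)][v]
                + (1 - wr) * wc * luts[(ri, cj)][v]
                + wr * (1 - wc) * luts[(rj, ci)][v]
                + wr * wc * luts[(rj, cj)][v]
            )
            out[r, c] = min(255, max(0, int(np.floor(blend + 0.5))))
    return out


def ssim_window_oracle(x, y, window=11, sigma=1.5, k1=0.01, k2=0.03, L=255.0):
    """SSIM by explicit per-window weighted statistics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = window // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g1, g1)
    w /= w.sum()
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    c3 = c2 / 2
    vals = []
    for r in range(half, x.shape[0] - half):
        for c in range(half, x.shape[1] - half):
            wx = x[r - half:r + half + 1, c - half:c + half + 1]
            wy = y[r - half:r + half + 1, c - half:c + half + 1]
            mx = float((w * wx).sum())
            my = float((w * wy).sum())
            vx = max(float((w * wx * wx).sum()) - mx * mx, 0.0)
            vy = max(float((w * wy * wy).sum()) - my * my, 0.0)
            cov = float((w * wx * wy).sum()) - mx * my
            sx, sy = np.sqrt(vx), np.sqrt(vy)
            l = (2 * mx * my + c1) / (mx * mx + my * my + c1)
            cterm = (2 * sx * sy + c2) / (vx + vy + c2)
            s = (cov + c3) / (sx * sy + c3)
            vals.append(l * cterm * s)
    return float(np.mean(vals))


def matern25_oracle(a, b, length_scales):
    """Matern-2.5 kernel via explicit distance loops."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    K = np.empty((len(a), len(b)))
    for i in range(len(a)):
        for j in range(len(b)):
            d = np.sqrt(np.sum(((a[i] - b[j]) / length_scales) ** 2))
            sd = np.sqrt(5.0) * d
            K[i, j] = (1 + sd + sd * sd / 3.0) * np.exp(-sd)
    return K


def gp_posterior_oracle(X, y, xq, length_scales, alpha):
    """Textbook GP posterior via an explicit matrix inverse."""
    K = matern25_oracle(X, X, length_scales) + alpha * np.eye(len(X))
    Kinv = np.linalg.inv(K)
    ks = matern25_oracle(np.atleast_2d(xq), X, length_scales)
    mean = ks @ Kinv @ y
    var = 1.0 - np.einsum("ij,jk,ik->i", ks, Kinv, ks)
    return mean, np.sqrt(np.maximum(var, 0.0))


def ei_quadrature_oracle(mean, sd, best, xi):
    """Expected improvement by numerical integration of the posterior."""
    def integrand(f):
        return max(f - best - xi, 0.0) * norm.pdf(f, loc=mean, scale=sd)

    lo = mean - 12 * sd
    hi = mean + 12 * sd
    val, _ = integrate.quad(integrand, lo, hi, limit=400)
    return val


def ggd_samples(rng, shape, scale, n):
    """Draws from a symmetric generalized Gaussian with given shape."""
    g = rng.gamma(1.0 / shape, 1.0, size=n)
    return scale * np.sign(rng.uniform(-1, 1, size=n)) * g ** (1.0 / shape)
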
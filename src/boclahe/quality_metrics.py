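"""Full-reference SSIM and no-reference BRISQUE features, combined into
the scalar objective that Bayesian optimization maximizes.

SSIM follows the three-term form ``l^alpha * c^beta * s^gamma`` with an
11x11 Gaussian window (sigma 1.5) and the usual stabilization constants
(K1=0.01, K2=0.03 on an 8-bit dynamic range).  Only windows fully inside
the evaluated region contribute ('valid' windows).

The BRISQUE front end computes mean-subtracted contrast-normalized
(MSCN) coefficients from 7x7 Gaussian local statistics, fits a
(possibly asymmetric) generalized Gaussian to the MSCN field and to its
four pairwise-product neighbor fields at two scales, yielding the
standard 36-feature vector.  Instead of a trained support-vector
regressor, the score is a Mahalanobis distance to reference statistics
packaged with this module (computed once from a pristine phantom
corpus); an external model file with the same JSON layout can be
substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.signal import convolve2d
from scipy.special import gamma as gamma_fn

from boclahe.errors import (
    ArgumentError,
    DegenerateInputError,
    ModelError,
    SizeError,
)

__all__ = [
    "SsimConfig",
    "SsimResult",
    "AggdParams",
    "BrisqueFeatures",
    "ObjectiveConfig",
    "QualityModel",
    "ssim",
    "mscn",
    "fit_aggd",
    "brisque_features",
    "brisque_score",
    "objective",
    "default_quality_model",
]


# ---------------------------------------------------------------------------
# SSIM


@dataclass(frozen=True)
class SsimConfig:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ArgumentError("SSIM exponents must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ArgumentError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ArgumentError("stabilization constants must be > 0")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


@dataclass(frozen=True)
class SsimResult:
    score: float
    luminance: float
    contrast: float
    structure: float


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _mask_bbox(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def ssim(x, y, cfg: SsimConfig | None = None, mask=None) -> SsimResult:
    """Structural similarity of two same-shape 8-bit images.

    With ``mask`` given, both images are cropped to the mask's bounding
    box first.  The score is the mean over valid windows of
    ``l^alpha * c^beta * s^gamma``; it is 1.0 for identical inputs and
    symmetric when all exponents are 1.
    """
    if cfg is None:
        cfg = SsimConfig()
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ArgumentError("images must have the same shape")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != xa.shape:
            raise ArgumentError("mask shape must match images")
        if not m.any():
            raise ArgumentError("mask is empty")
        r0, r1, c0, c1 = _mask_bbox(m)
        xa = xa[r0:r1, c0:c1]
        ya = ya[r0:r1, c0:c1]
    if min(xa.shape) < cfg.window:
        raise SizeError("evaluated region smaller than the SSIM window")

    k = _gaussian_kernel(cfg.window, cfg.sigma)
    mu_x = convolve2d(xa, k, mode="valid")
    mu_y = convolve2d(ya, k, mode="valid")
    mu_xx = convolve2d(xa * xa, k, mode="valid")
    mu_yy = convolve2d(ya * ya, k, mode="valid")
    mu_xy = convolve2d(xa * ya, k, mode="valid")
    var_x = np.maximum(mu_xx - mu_x**2, 0.0)
    var_y = np.maximum(mu_yy - mu_y**2, 0.0)
    sd_x = np.sqrt(var_x)
    sd_y = np.sqrt(var_y)
    cov = mu_xy - mu_x * mu_y

    l = (2 * mu_x * mu_y + cfg.c1) / (mu_x**2 + mu_y**2 + cfg.c1)
    c = (2 * sd_x * sd_y + cfg.c2) / (var_x + var_y + cfg.c2)
    s = (cov + cfg.c3) / (sd_x * sd_y + cfg.c3)

    def _pow(t, e):
        if e == 1.0:
            return t
        return np.sign(t) * np.abs(t) ** e

    per_window = _pow(l, cfg.alpha) * _pow(c, cfg.beta) * _pow(s, cfg.gamma)
    return SsimResult(
        score=float(per_window.mean()),
        luminance=float(l.mean()),
        contrast=float(c.mean()),
        structure=float(s.mean()),
    )


# ---------------------------------------------------------------------------
# BRISQUE


@dataclass(frozen=True)
class AggdParams:
    """Asymmetric generalized Gaussian parameters from moment matching."""

    shape: float
    scale_left: float
    scale_right: float
    mean_offset: float


_MSCN_KERNEL = _gaussian_kernel(7, 7.0 / 6.0)
_MSCN_STABILIZER = 1.0  # on the 0-255 intensity scale

# tabulated generalized-Gaussian ratio function over shape in [0.2, 10]
_GGD_SHAPES = np.arange(0.2, 10.001, 0.001)
_GGD_RATIO = (
    gamma_fn(2.0 / _GGD_SHAPES) ** 2
    / (gamma_fn(1.0 / _GGD_SHAPES) * gamma_fn(3.0 / _GGD_SHAPES))
)


def mscn(image) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients.

    Local mean and deviation come from a 7x7 Gaussian window; the
    denominator is stabilized by +1 on the 8-bit scale.  Same shape as
    the input.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 7:
        raise SizeError("image must be 2D and at least 7x7")
    mu = convolve2d(img, _MSCN_KERNEL, mode="same", boundary="symm")
    mu2 = convolve2d(img * img, _MSCN_KERNEL, mode="same", boundary="symm")
    sigma = np.sqrt(np.maximum(mu2 - mu * mu, 0.0))
    return (img - mu) / (sigma + _MSCN_STABILIZER)


def fit_aggd(samples) -> AggdParams:
    """Moment-matching AGGD fit.

    The ratio of mean absolute deviation to standard deviation is
    inverted through the tabulated generalized-Gaussian ratio function
    (shape grid [0.2, 10], step 0.001).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise ArgumentError("need at least 100 samples")
    if np.var(x) == 0.0:
        raise DegenerateInputError("samples have zero variance")
    return _fit_aggd_unchecked(x)


def _fit_aggd_unchecked(x: np.ndarray) -> AggdParams:
    left = x[x < 0]
    right = x[x >= 0]
    # denominators guarded: an all-positive (or all-negative) sample set
    # still yields finite parameters
    sig_l = np.sqrt(np.mean(left**2)) if left.size else 0.0
    sig_r = np.sqrt(np.mean(right**2)) if right.size else 0.0
    eps = 1e-12
    gamma_hat = (sig_l + eps) / (sig_r + eps)
    m1 = np.mean(np.abs(x))
    m2 = np.mean(x**2)
    r_hat = m1**2 / (m2 + eps)
    r_hat_norm = (
        r_hat
        * (gamma_hat**3 + 1.0)
        * (gamma_hat + 1.0)
        / ((gamma_hat**2 + 1.0) ** 2 + eps)
    )
    shape = float(_GGD_SHAPES[np.argmin((_GGD_RATIO - r_hat_norm) ** 2)])
    conv = np.sqrt(gamma_fn(1.0 / shape) / gamma_fn(3.0 / shape))
    scale_l = float(max(sig_l * conv, eps))
    scale_r = float(max(sig_r * conv, eps))
    mean_offset = float(
        (scale_r - scale_l) * gamma_fn(2.0 / shape) / gamma_fn(1.0 / shape)
    )
    return AggdParams(shape=shape, scale_left=scale_l, scale_right=scale_r,
                      mean_offset=mean_offset)


def _fit_aggd_safe(x: np.ndarray) -> AggdParams:
    if np.var(x) == 0.0:
        return AggdParams(shape=2.0, scale_left=1e-12, scale_right=1e-12,
                          mean_offset=0.0)
    return _fit_aggd_unchecked(x)


@dataclass(frozen=True)
class BrisqueFeatures:
    """Exactly 36 finite natural-scene-statistics features."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (36,):
            raise ArgumentError("BRISQUE feature vector must have 36 entries")
        if not np.all(np.isfinite(v)):
            raise ArgumentError("BRISQUE features must be finite")
        object.__setattr__(self, "values", v)


def _box_downsample(img: np.ndarray) -> np.ndarray:
    r, c = img.shape
    img = img[: r - (r % 2), : c - (c % 2)]
    return 0.25 * (img[0::2, 0::2] + img[0::2, 1::2] + img[1::2, 0::2] + img[1::2, 1::2])


def _scale_features(img: np.ndarray) -> list[float]:
    m = mscn(img)
    flat = m.ravel()
    p = _fit_aggd_safe(flat)
    feats = [p.shape, (p.scale_left**2 + p.scale_right**2) / 2.0]
    pairs = (
        m[:, :-1] * m[:, 1:],        # horizontal
        m[:-1, :] * m[1:, :],        # vertical
        m[:-1, :-1] * m[1:, 1:],     # main diagonal
        m[:-1, 1:] * m[1:, :-1],     # secondary diagonal
    )
    for prod in pairs:
        q = _fit_aggd_safe(prod.ravel())
        feats.extend([q.shape, q.mean_offset, q.scale_left**2, q.scale_right**2])
    return feats


def brisque_features(image) -> BrisqueFeatures:
    """The 36-element BRISQUE feature vector (two scales, 18 each)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise SizeError("image must be 2D and at least 32x32")
    feats = _scale_features(img)
    feats += _scale_features(_box_downsample(img))
    return BrisqueFeatures(values=np.asarray(feats, dtype=float))


# ---------------------------------------------------------------------------
# quality model and scoring


@dataclass(frozen=True)
class QualityModel:
    """Reference feature statistics: 36-vector mean, 36x36 covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mu.shape != (36,) or cov.shape != (36, 36):
            raise ModelError("quality model must have a 36-vector mean and 36x36 covariance")
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "covariance", cov)

    @classmethod
    def from_json_file(cls, path) -> "QualityModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean=np.asarray(d["mean"]), covariance=np.asarray(d["covariance"]))

    def to_json_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean.tolist(),
                       "covariance": self.covariance.tolist()}, fh)


_DEFAULT_MODEL: QualityModel | None = None


def default_quality_model() -> QualityModel:
    """Packaged statistics computed once from a pristine phantom corpus."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        text = resources.files("boclahe").joinpath("data/quality_model.json").read_text()
        d = json.loads(text)
        _DEFAULT_MODEL = QualityModel(
            mean=np.asarray(d["mean"]), covariance=np.asarray(d["covariance"])
        )
    return _DEFAULT_MODEL


def brisque_score(features: BrisqueFeatures, model: QualityModel | None = None) -> float:
    """Mahalanobis distance of a feature vector to the reference statistics.

    Non-negative; 0 exactly at the model mean; lower = better quality.
    """
    if model is None:
        model = default_quality_model()
    d = features.values - model.mean
    try:
        chol = np.linalg.cholesky(model.covariance)
    except np.linalg.LinAlgError as exc:
        raise ModelError("quality model covariance is not positive definite") from exc
    z = np.linalg.solve(chol, d)
    return float(np.sqrt(z @ z))


# ---------------------------------------------------------------------------
# combined objective


@dataclass(frozen=True)
class ObjectiveConfig:
    w_ssim: float = 1.0
    w_brisque: float = 1.0
    brisque_norm: float = 100.0

    def __post_init__(self):
        if self.w_ssim < 0 or self.w_brisque < 0:
            raise ArgumentError("weights must be >= 0")
        if self.w_ssim == 0 and self.w_brisque == 0:
            raise ArgumentError("at least one weight must be positive")
        if self.brisque_norm <= 0:
            raise ArgumentError("brisque_norm must be > 0")


def objective_components(original, enhanced, mask, cfg: ObjectiveConfig | None = None,
                         model: QualityModel | None = None) -> dict:
    """SSIM term, BRISQUE distance and the combined scalar, as a dict."""
    if cfg is None:
        cfg = ObjectiveConfig()
    orig = np.asarray(original)
    enh = np.asarray(enhanced)
    if orig.shape != enh.shape:
        raise ArgumentError("original and enhanced must have the same shape")
    m = np.asarray(mask, dtype=bool)
    ssim_val = ssim(orig, enh, mask=m).score
    r0, r1, c0, c1 = _mask_bbox(m)
    bscore = brisque_score(brisque_features(enh[r0:r1, c0:c1]), model)
    combined = cfg.w_ssim * ssim_val - cfg.w_brisque * bscore / cfg.brisque_norm
    return {"ssim": ssim_val, "brisque": bscore, "objective": combined}


def objective(original, enhanced, mask, cfg: ObjectiveConfig | None = None,
              model: QualityModel | None = None) -> float:
    """w_ssim * SSIM - w_brisque * BRISQUE_distance / brisque_norm (larger = better)."""
    return objective_components(original, enhanced, mask, cfg, model)["objective"]
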
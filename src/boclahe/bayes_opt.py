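"""Gaussian-process surrogate, UCB/EI acquisition, and the sequential
optimization loop over the CLAHE parameter box.

The surrogate is exact GP regression with a Matern-2.5 kernel (unit
amplitude, per-dimension length scales) on inputs scaled to the unit
box.  Kernel length scales are fitted by maximizing the log marginal
likelihood with multi-restart L-BFGS-B over log length scales; targets
are optionally centered and scaled (``normalize_y``).  Defaults mirror
the standard BO toolchain settings: 25 random initial points, 25 BO
iterations, UCB with kappa = 2.576 (EI with xi = 0.01 by flag), noise
alpha = 1e-6, 5 restarts, normalize_y = True.

All randomness flows from one seed through spawned NumPy generators, so
a full run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import norm

from boclahe.errors import ArgumentError, StateError

__all__ = [
    "Bounds",
    "GpConfig",
    "GpModel",
    "AcquisitionSpec",
    "OptSettings",
    "TraceRecord",
    "Trace",
    "gp_fit",
    "gp_predict",
    "acquisition_value",
    "suggest_next",
    "optimize",
]


@dataclass(frozen=True)
class Bounds:
    """Closed search intervals for the two CLAHE parameters."""

    clip_limit: tuple = (1.0, 255.0)
    tile_grid: tuple = (8.0, 32.0)

    def __post_init__(self):
        for name in ("clip_limit", "tile_grid"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ArgumentError(f"{name} bounds must satisfy lower < upper")

    def as_array(self) -> np.ndarray:
        return np.asarray([self.clip_limit, self.tile_grid], dtype=float)


@dataclass(frozen=True)
class GpConfig:
    length_scale_bounds: tuple = (1e-2, 1e3)
    noise_alpha: float = 1e-6
    normalize_y: bool = True
    n_restarts: int = 5

    def __post_init__(self):
        if self.noise_alpha <= 0:
            raise ArgumentError("noise_alpha must be > 0")
        if self.n_restarts < 1:
            raise ArgumentError("n_restarts must be >= 1")


@dataclass(frozen=True)
class AcquisitionSpec:
    kind: str = "ucb"
    kappa: float = 2.576
    xi: float = 0.01

    def __post_init__(self):
        if self.kind not in ("ucb", "ei"):
            raise ArgumentError("acquisition kind must be 'ucb' or 'ei'")
        if self.kappa <= 0:
            raise ArgumentError("kappa must be > 0")
        if self.xi < 0:
            raise ArgumentError("xi must be >= 0")


@dataclass(frozen=True)
class OptSettings:
    init_points: int = 25
    n_iter: int = 25
    seed: int = 0
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)

    def __post_init__(self):
        if self.init_points < 1:
            raise ArgumentError("init_points must be >= 1")
        if self.n_iter < 0:
            raise ArgumentError("n_iter must be >= 0")


def matern25(a: np.ndarray, b: np.ndarray, length_scales: np.ndarray) -> np.ndarray:
    """Matern-2.5 kernel matrix with per-dimension length scales, amplitude 1."""
    diff = a[:, None, :] - b[None, :, :]
    d = np.sqrt(np.sum((diff / length_scales) ** 2, axis=-1))
    sd = np.sqrt(5.0) * d
    return (1.0 + sd + sd**2 / 3.0) * np.exp(-sd)


def _merge_duplicates(X: np.ndarray, y: np.ndarray):
    """Average targets of exactly duplicated rows (keeps K well-posed)."""
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    if len(uniq) == len(X):
        return X, y
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, y)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


class GpModel:
    """Exact GP posterior over objective values on the scaled unit box."""

    def __init__(self, bounds: Bounds, cfg: GpConfig | None = None):
        self.bounds = bounds
        self.cfg = cfg if cfg is not None else GpConfig()
        self._fitted = False

    # -- scaling -----------------------------------------------------------
    def _scale(self, X: np.ndarray) -> np.ndarray:
        b = self.bounds.as_array()
        return (np.atleast_2d(X) - b[:, 0]) / (b[:, 1] - b[:, 0])

    # -- marginal likelihood ----------------------------------------------
    def _neg_log_marginal_likelihood(self, log_ls: np.ndarray) -> float:
        ls = np.exp(log_ls)
        K = matern25(self._Xs, self._Xs, ls)
        K[np.diag_indices_from(K)] += self.cfg.noise_alpha
        try:
            L = cholesky(K, lower=True)
        except np.linalg.LinAlgError:
            return 1e25
        alpha = cho_solve((L, True), self._yn)
        n = len(self._yn)
        lml = (
            -0.5 * float(self._yn @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        return -lml

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, rng: np.random.Generator | None = None) -> "GpModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y) or len(X) == 0:
            raise ArgumentError("X and y must be nonempty and the same length")
        if not np.all(np.isfinite(y)):
            raise ArgumentError("targets must be finite")
        X, y = _merge_duplicates(X, y)
        self.X_train = X
        self.y_train = y
        self._Xs = self._scale(X)

        if self.cfg.normalize_y:
            self._y_mean = float(y.mean())
            std = float(y.std())
            self._y_std = std if std > 0 else 1.0  # zero-variance: skip scaling
        else:
            self._y_mean, self._y_std = 0.0, 1.0
        self._yn = (y - self._y_mean) / self._y_std

        lo, hi = np.log(self.cfg.length_scale_bounds[0]), np.log(self.cfg.length_scale_bounds[1])
        ndim = X.shape[1]
        starts = [np.zeros(ndim)]  # length scale 1 on the unit box
        if rng is None:
            rng = np.random.default_rng(0)
        for _ in range(self.cfg.n_restarts - 1):
            starts.append(rng.uniform(lo, hi, size=ndim))
        best_val, best_ls = np.inf, np.ones(ndim)
        for x0 in starts:
            res = minimize(
                self._neg_log_marginal_likelihood,
                x0,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * ndim,
            )
            if res.fun < best_val:
                best_val, best_ls = res.fun, np.exp(res.x)
        self.length_scales = best_ls
        self._finalize()
        return self

    def fit_fixed(self, X, y, length_scales) -> "GpModel":
        """Fit with fixed kernel hyperparameters (no LML optimization)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y) or len(X) == 0:
            raise ArgumentError("X and y must be nonempty and the same length")
        X, y = _merge_duplicates(X, y)
        self.X_train = X
        self.y_train = y
        self._Xs = self._scale(X)
        if self.cfg.normalize_y:
            self._y_mean = float(y.mean())
            std = float(y.std())
            self._y_std = std if std > 0 else 1.0
        else:
            self._y_mean, self._y_std = 0.0, 1.0
        self._yn = (y - self._y_mean) / self._y_std
        self.length_scales = np.asarray(length_scales, dtype=float)
        self._finalize()
        return self

    def _finalize(self):
        K = matern25(self._Xs, self._Xs, self.length_scales)
        K[np.diag_indices_from(K)] += self.cfg.noise_alpha
        self._chol = cho_factor(K, lower=True)
        self._alpha = cho_solve(self._chol, self._yn)
        self._fitted = True

    # -- prediction --------------------------------------------------------
    def predict(self, x):
        """Posterior mean and standard deviation at one or more points."""
        if not self._fitted:
            raise StateError("GP model is not fitted")
        Xq = self._scale(np.asarray(x, dtype=float))
        Ks = matern25(Xq, self._Xs, self.length_scales)
        mean_n = Ks @ self._alpha
        v = solve_triangular(self._chol[0], Ks.T, lower=True)
        var_n = np.maximum(1.0 - np.sum(v**2, axis=0), 0.0)
        mean = mean_n * self._y_std + self._y_mean
        sd = np.sqrt(var_n) * self._y_std
        if np.ndim(x) == 1:
            return float(mean[0]), float(sd[0])
        return mean, sd


def gp_fit(X, y, cfg: GpConfig | None = None, bounds: Bounds | None = None,
           rng: np.random.Generator | None = None) -> GpModel:
    """Fit a GP surrogate; length scales maximize the restarted LML."""
    if bounds is None:
        bounds = Bounds()
    model = GpModel(bounds, cfg)
    return model.fit(X, y, rng=rng)


def gp_predict(model: GpModel, x):
    """Posterior (mean, standard deviation) at ``x``."""
    return model.predict(x)


def acquisition_value(mean, sd, spec: AcquisitionSpec, best_so_far: float):
    """UCB = mean + kappa*sd; EI with margin xi (0 where sd = 0)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ArgumentError("standard deviation must be >= 0")
    if spec.kind == "ucb":
        out = mean + spec.kappa * sd
    else:
        impr = mean - best_so_far - spec.xi
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, impr / np.where(sd > 0, sd, 1.0), 0.0)
        out = np.where(sd > 0, impr * norm.cdf(z) + sd * norm.pdf(z), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def suggest_next(model: GpModel, bounds: Bounds, spec: AcquisitionSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Acquisition argmax over the box: 1,000 seeded random candidates
    plus L-BFGS-B refinement from the best 5."""
    if not model._fitted:
        raise StateError("GP model is not fitted")
    b = bounds.as_array()
    best_y = float(np.max(model.y_train))
    cand = rng.uniform(b[:, 0], b[:, 1], size=(1000, len(b)))
    mean, sd = model.predict(cand)
    acq = acquisition_value(mean, sd, spec, best_y)
    order = np.argsort(acq)[::-1]

    def neg_acq(x):
        m, s = model.predict(x)
        return -acquisition_value(m, s, spec, best_y)

    best_x = cand[order[0]]
    best_a = acq[order[0]]
    incumbent = model.X_train[int(np.argmax(model.y_train))]
    starts = [cand[idx] for idx in order[:5]] + [incumbent]
    for x0 in starts:
        res = minimize(neg_acq, x0, method="L-BFGS-B",
                       bounds=[tuple(row) for row in b])
        if -res.fun > best_a:
            best_a = -res.fun
            best_x = np.clip(res.x, b[:, 0], b[:, 1])
    return np.asarray(best_x, dtype=float)


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    phase: str  # 'init' or 'bo'
    clip_limit: float
    tile_grid: float
    objective: float
    extras: dict = field(default_factory=dict)


@dataclass
class Trace:
    """Ordered record of all objective evaluations in one run."""

    records: list
    best_params: tuple
    best_value: float

    @classmethod
    def from_records(cls, records) -> "Trace":
        best = max(records, key=lambda r: r.objective)
        return cls(records=list(records),
                   best_params=(best.clip_limit, best.tile_grid),
                   best_value=best.objective)


def optimize(eval_fn, bounds: Bounds, settings: OptSettings,
             gp_cfg: GpConfig | None = None) -> Trace:
    """Sequential BO: seeded random initialization then fit/suggest/evaluate.

    ``eval_fn(clip_limit, tile_grid) -> objective`` (larger = better) must
    be total over the bounds; it may return a ``(value, extras-dict)``
    pair to attach per-evaluation metadata to the trace.  If ``eval_fn``
    raises, the partial trace is attached to the exception as
    ``exc.partial_trace``.
    """
    if gp_cfg is None:
        gp_cfg = GpConfig()
    b = bounds.as_array()
    root = np.random.SeedSequence(settings.seed)
    ss_init, ss_fit, ss_sugg = root.spawn(3)
    rng_init = np.random.default_rng(ss_init)
    fit_seeds = ss_fit.spawn(settings.n_iter)
    sugg_seeds = ss_sugg.spawn(settings.n_iter)

    records: list[TraceRecord] = []

    def _evaluate(x, idx, phase):
        try:
            out = eval_fn(float(x[0]), float(x[1]))
        except Exception as exc:
            exc.partial_trace = Trace.from_records(records) if records else Trace([], (np.nan, np.nan), -np.inf)
            raise
        if isinstance(out, tuple):
            value, extras = out
        else:
            value, extras = out, {}
        records.append(TraceRecord(iteration=idx, phase=phase,
                                   clip_limit=float(x[0]), tile_grid=float(x[1]),
                                   objective=float(value), extras=dict(extras)))

    X_init = rng_init.uniform(b[:, 0], b[:, 1], size=(settings.init_points, len(b)))
    for i, x in enumerate(X_init):
        _evaluate(x, i, "init")

    for j in range(settings.n_iter):
        X = np.asarray([[r.clip_limit, r.tile_grid] for r in records])
        y = np.asarray([r.objective for r in records])
        model = GpModel(bounds, gp_cfg).fit(X, y, rng=np.random.default_rng(fit_seeds[j]))
        x_next = suggest_next(model, bounds, settings.acquisition,
                              np.random.default_rng(sugg_seeds[j]))
        _evaluate(x_next, settings.init_points + j, "bo")

    return Trace.from_records(records)
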
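"""Hyperparameter search over the calibration parameters (lambda, gamma).

Two strategies:

* exhaustive grid search over a lattice with user-chosen step sizes
  (typically 0.1 for lambda and 0.2 for gamma on [0, 1] x [0, 1]);
* Bayesian optimization: a Gaussian-process surrogate (Matern 5/2 kernel)
  with the Expected Improvement acquisition function, seeded by a
  quasi-random initial design.  Wide positive ranges such as
  [1e-3, 1e1] are searched on a log10 scale.

The objective is maximized; it is typically episode-set mean accuracy
evaluated on a FIXED episode seed across all trials, so the search compares
parameter settings on identical episodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .errors import ValidationError
from .pdfc import CalibrationParams

Objective = Callable[[float, float], float]


@dataclass(frozen=True)
class SearchSpace:
    """Rectangular (lambda, gamma) search domain."""

    lam_bounds: tuple[float, float] = (0.0, 1.0)
    gamma_bounds: tuple[float, float] = (0.0, 1.0)
    scale: str = "linear"  # or "log": sample/model both axes in log10 space
    grid_steps: tuple[float, float] | None = None  # (lam step, gamma step)

    def validate(self) -> "SearchSpace":
        for name, (lo, hi) in (("lam", self.lam_bounds), ("gamma", self.gamma_bounds)):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValidationError(f"{name}_bounds must be finite with lower < upper")
        if self.scale not in ("linear", "log"):
            raise ValidationError("scale must be 'linear' or 'log'")
        if self.scale == "log" and (self.lam_bounds[0] <= 0 or self.gamma_bounds[0] <= 0):
            raise ValidationError("log scale requires strictly positive bounds")
        if self.grid_steps is not None and any(s <= 0 for s in self.grid_steps):
            raise ValidationError("grid steps must be positive")
        return self


@dataclass
class SearchResult:
    """Outcome of a search: best parameters and the full trial log."""

    best_params: CalibrationParams
    best_objective: float
    trials: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_lam": self.best_params.lam,
            "best_gamma": self.best_params.gamma,
            "best_objective": self.best_objective,
            "trials": [
                {"lam": l, "gamma": g, "objective": o} for l, g, o in self.trials
            ],
        }


def _lattice(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive lattice lo, lo+step, ..., hi (endpoint kept even when the
    range is not an exact multiple of the step)."""
    n = int(np.floor((hi - lo) / step + 1e-9))
    pts = lo + step * np.arange(n + 1)
    pts = np.round(pts, 12)
    if pts[-1] < hi - 1e-9:
        pts = np.append(pts, hi)
    return pts


def grid_search(
    objective: Objective,
    space: SearchSpace,
    m: int = 10,
) -> SearchResult:
    """Evaluate every lattice point and return the exhaustive argmax.

    Iteration is row-major, lambda outer, gamma inner; ties keep the first
    point encountered.
    """
    space.validate()
    if space.grid_steps is None:
        raise ValidationError("grid_search requires space.grid_steps")
    lam_pts = _lattice(*space.lam_bounds, space.grid_steps[0])
    gam_pts = _lattice(*space.gamma_bounds, space.grid_steps[1])
    if lam_pts.size == 0 or gam_pts.size == 0:
        raise ValidationError("empty grid")
    trials: list[tuple[float, float, float]] = []
    best = (-np.inf, 0.0, 0.0)
    for lam in lam_pts:
        for gam in gam_pts:
            val = float(objective(float(lam), float(gam)))
            trials.append((float(lam), float(gam), val))
            if val > best[0]:  # strict: first-encountered wins ties
                best = (val, float(lam), float(gam))
    return SearchResult(
        best_params=CalibrationParams(m=m, lam=best[1], gamma=best[2]),
        best_objective=best[0],
        trials=trials,
    )


# ---------------------------------------------------------------------------
# Bayesian optimization: GP surrogate + Expected Improvement
# ---------------------------------------------------------------------------

_N_INITIAL = 10  # quasi-random initial design, counted within n_iterations
_N_CANDIDATES = 2000  # random candidates scored by EI per iteration


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    """EI for maximization: E[max(f - best, 0)] under N(mu, sigma^2)."""
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_search(
    objective: Objective,
    space: SearchSpace,
    n_iterations: int = 100,
    seed: int = 0,
    m: int = 10,
) -> SearchResult:
    """GP-surrogate + Expected Improvement loop, maximizing the objective.

    ``n_iterations`` counts total objective evaluations, including the
    quasi-random (Halton) initial design of 10 points.  The result is the
    best OBSERVED objective, never a surrogate prediction.  Deterministic
    under a fixed seed.  A trial returning a non-finite value is recorded
    as failed and skipped; if every trial fails an error is raised.
    """
    space.validate()
    if n_iterations < 2:
        raise ValidationError("bayes_search requires n_iterations >= 2")
    rng = np.random.default_rng(seed)

    lo = np.array([space.lam_bounds[0], space.gamma_bounds[0]])
    hi = np.array([space.lam_bounds[1], space.gamma_bounds[1]])
    if space.scale == "log":
        lo, hi = np.log10(lo), np.log10(hi)

    def to_params(u: np.ndarray) -> tuple[float, float]:
        x = 10.0**u if space.scale == "log" else u
        return float(x[0]), float(x[1])

    # initial quasi-random design
    n_init = min(_N_INITIAL, n_iterations)
    halton = qmc.Halton(d=2, scramble=True, seed=int(rng.integers(2**31)))
    init = lo + halton.random(n_init) * (hi - lo)

    xs: list[np.ndarray] = []
    ys: list[float] = []
    trials: list[tuple[float, float, float]] = []

    def evaluate(u: np.ndarray) -> None:
        lam, gam = to_params(u)
        val = float(objective(lam, gam))
        if np.isfinite(val):
            xs.append(u)
            ys.append(val)
            trials.append((lam, gam, val))
        else:
            warnings.warn(
                f"objective non-finite at lam={lam:.4g}, gamma={gam:.4g}; "
                "trial skipped",
                stacklevel=3,
            )

    for u in init:
        evaluate(u)

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.ones(2), length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-6, (1e-10, 1e-1))
    )
    span = hi - lo
    for _ in range(n_iterations - n_init):
        if len(xs) >= 2:
            x_arr = (np.array(xs) - lo) / span  # unit cube for GP stability
            y_arr = np.array(ys)
            y_mean, y_std = y_arr.mean(), max(y_arr.std(), 1e-12)
            gp = GaussianProcessRegressor(
                kernel=kernel,
                normalize_y=False,
                n_restarts_optimizer=1,
                random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(x_arr, (y_arr - y_mean) / y_std)
            cand = rng.random((_N_CANDIDATES, 2))
            mu, sigma = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sigma, (max(ys) - y_mean) / y_std)
            u_next = lo + cand[int(np.argmax(ei))] * span
        else:  # all trials so far failed: fall back to random exploration
            u_next = lo + rng.random(2) * span
        evaluate(u_next)

    if not ys:
        raise ValidationError("every objective evaluation failed (non-finite)")
    k = int(np.argmax(ys))
    lam, gam, val = trials[k]
    return SearchResult(
        best_params=CalibrationParams(m=m, lam=lam, gamma=gam),
        best_objective=val,
        trials=trials,
    )
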
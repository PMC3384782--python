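"""Parameter containers for the joint model.

``GrowthParameters`` holds the longitudinal side: the growth-coefficient
matrix ``beta`` (r x q, with structural zeros fixed by the trajectory spec),
the random-effect covariance ``Sigma`` (r x r) and the measurement-error
variance ``sigma2``.  ``SurvivalParameters`` holds the hazard side: the
log-hazard covariate coefficients ``alpha``, the link coefficients ``gamma``
(a scalar for the trajectory link, a length-r vector for the shared
random-effects link) and a piecewise-constant baseline hazard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PiecewiseConstantHazard", "GrowthParameters", "SurvivalParameters"]


class PiecewiseConstantHazard:
    """Piecewise-constant hazard ``h(t)`` with closed-form cumulative hazard.

    Parameters
    ----------
    breaks : array-like
        Interior breakpoints ``0 < t_1 < ... < t_{K-1}``; the hazard is
        constant on ``[0, t_1), [t_1, t_2), ..., [t_{K-1}, inf)``.
    heights : array-like, length ``len(breaks) + 1``
        Strictly positive hazard heights per piece.  Beyond the last
        breakpoint the final height extends to infinity, so the cumulative
        hazard is unbounded and inverse-transform sampling always terminates.
    """

    def __init__(self, breaks, heights):
        breaks = np.atleast_1d(np.asarray(breaks, dtype=float))
        heights = np.atleast_1d(np.asarray(heights, dtype=float))
        if breaks.size and (np.any(np.diff(breaks) <= 0) or breaks[0] <= 0):
            raise ValueError("breaks must be strictly increasing and positive")
        if heights.size != breaks.size + 1:
            raise ValueError("need len(breaks) + 1 heights")
        if np.any(heights <= 0):
            raise ValueError("hazard heights must be positive")
        self.breaks = breaks
        self.heights = heights
        # piece edges including 0; last piece open-ended
        self._edges = np.concatenate([[0.0], breaks])

    @classmethod
    def constant(cls, rate):
        return cls(np.empty(0), [rate])

    @property
    def n_pieces(self) -> int:
        return self.heights.size

    def piece_index(self, t):
        """Index of the piece containing ``t`` (right-open intervals)."""
        return np.clip(np.searchsorted(self._edges, np.asarray(t, float),
                                       side="right") - 1, 0, self.n_pieces - 1)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.heights[self.piece_index(t)]

    def cumulative(self, t):
        """``H(t) = int_0^t h(s) ds``, exact."""
        t = np.asarray(t, dtype=float)
        lo = self._edges  # (K,)
        hi = np.concatenate([self.breaks, [np.inf]])
        expo = np.clip(np.minimum(t[..., None], hi) - lo, 0.0, None)
        return expo @ self.heights

    def exposure(self, start, stop):
        """Per-piece exposure of the interval ``[start, stop)``; shape (..., K)."""
        start = np.asarray(start, dtype=float)
        stop = np.asarray(stop, dtype=float)
        lo = self._edges
        hi = np.concatenate([self.breaks, [np.inf]])
        return np.clip(np.minimum(stop[..., None], hi)
                       - np.maximum(start[..., None], lo), 0.0, None)

    def invert_cumulative(self, target):
        """Solve ``H(t) = target`` for ``t`` (scalar or array target >= 0)."""
        target = np.asarray(target, dtype=float)
        if self.breaks.size:
            cum_at_edges = np.concatenate([[0.0], self.cumulative(self.breaks)])
        else:
            cum_at_edges = np.array([0.0])
        idx = np.clip(np.searchsorted(cum_at_edges, target, side="right") - 1,
                      0, self.n_pieces - 1)
        return self._edges[idx] + (target - cum_at_edges[idx]) / self.heights[idx]

    def to_dict(self):
        return {"breaks": self.breaks.tolist(), "heights": self.heights.tolist()}

    def __repr__(self):
        return (f"PiecewiseConstantHazard(breaks={self.breaks.tolist()}, "
                f"heights={np.round(self.heights, 4).tolist()})")


@dataclass
class GrowthParameters:
    """Longitudinal parameters ``(beta, Sigma, sigma2)``.

    ``Sigma`` must be symmetric positive definite; a zero matrix is accepted
    only with ``allow_singular=True`` (degenerate test/simulation mode).
    """

    beta: np.ndarray
    Sigma: np.ndarray
    sigma2: float
    allow_singular: bool = False

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        r = self.beta.shape[0]
        if self.Sigma.shape != (r, r):
            raise ValueError(f"Sigma must be {r}x{r} to match beta")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        eig = np.linalg.eigvalsh(self.Sigma)
        if np.all(self.Sigma == 0):
            if not self.allow_singular:
                raise ValueError(
                    "Sigma is the zero matrix; pass allow_singular=True for the "
                    "degenerate (noise-free) simulation mode")
        elif eig[0] <= 0:
            raise ValueError(
                f"Sigma is not positive definite: smallest eigenvalue {eig[0]:.3e}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")

    @property
    def r(self) -> int:
        return self.beta.shape[0]

    def validate_mask(self, mask):
        """Check structural zeros of ``beta`` against a spec mask."""
        if np.any(self.beta[~np.asarray(mask, bool)] != 0):
            raise ValueError("beta has non-zero entries at structural zeros")


@dataclass
class SurvivalParameters:
    """Hazard parameters ``(alpha, gamma, baseline)``.

    ``gamma`` is a scalar under the trajectory link (association between the
    hazard and the current latent trajectory value) and a length-r vector
    under the shared random-effects link (one coefficient per random growth
    coefficient).
    """

    alpha: np.ndarray
    gamma: np.ndarray
    baseline: PiecewiseConstantHazard
    alpha_names: tuple = field(default=("z",))

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if len(self.alpha_names) != self.alpha.size:
            raise ValueError("alpha_names must match alpha length")

    def linear_predictor(self, X_s):
        """``X_s' alpha`` for one covariate row or a matrix of rows."""
        return np.asarray(X_s, dtype=float) @ self.alpha


def params_to_json(growth: GrowthParameters, survival: SurvivalParameters,
                   spec, link, path=None):
    """Serialize a full parameter set to JSON with named entries."""
    coef = spec.coef_names
    covs = spec.covariates
    out = {
        "spec": spec.name,
        "link": link,
        "beta": {f"{coef[m]}.{covs[j]}": float(growth.beta[m, j])
                 for m in range(spec.r) for j in range(spec.q)},
        "Sigma": np.asarray(growth.Sigma).tolist(),
        "sigma2": float(growth.sigma2),
        "alpha": {name: float(a) for name, a in
                  zip(survival.alpha_names, survival.alpha)},
        "gamma": np.asarray(survival.gamma).tolist(),
        "baseline": survival.baseline.to_dict(),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)
    return out
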
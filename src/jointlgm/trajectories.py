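"""Latent growth trajectory specifications.

Each subject's latent symptom trajectory is a low-order polynomial in time,

    eta_i(t) = f(t)' b_i,        b_i = beta X_i + zeta_i,

where ``f(t)`` is the polynomial basis ``(1, t)`` (linear) or ``(1, t, t^2)``
(quadratic), ``b_i`` is the subject-level random coefficient vector (intercept,
slope and, for quadratic shapes, curvature), ``X_i`` collects the constant and
binary baseline covariates, and ``beta`` is the coefficient matrix of the
growth sub-models.  A :class:`TrajectorySpec` fixes the shape and which
covariate enters which growth coefficient's sub-model; entries of ``beta``
outside that inclusion map are structural zeros that no estimation step may
perturb.

Five named presets are supported:

========  =========  ============================================
name      shape      treatment enters
========  =========  ============================================
``l_i``   linear     intercept only
``l_s``   linear     slope only
``l_is``  linear     intercept and slope
``q_s``   quadratic  slope only
``q_sq``  quadratic  slope and quadratic coefficient
========  =========  ============================================

For analyses with additional baseline covariates,
:func:`covariate_extended_spec` builds a quadratic spec in which every
covariate enters every sub-model except that treatment and pre-treatment
vitamin supplementation (``bf``) are excluded from the intercept sub-model:
the intercept is the pre-treatment status and cannot be affected by
post-baseline interventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectorySpec",
    "get_spec",
    "covariate_extended_spec",
    "basis_row",
    "beta_pattern",
    "trajectory_value",
    "fitted_mean_curve",
    "PRESETS",
]

COEF_NAMES = {"linear": ("intercept", "slope"), "quadratic": ("intercept", "slope", "quad")}


@dataclass(frozen=True)
class TrajectorySpec:
    """Shape of the growth curve plus the covariate inclusion map.

    Parameters
    ----------
    name : str
        Identifier (preset name or a custom label).
    shape : {"linear", "quadratic"}
        Polynomial order of ``f(t)``; the number of random coefficients is
        ``r = 2`` or ``3``.
    inclusion : dict
        Maps each growth-coefficient name (``intercept``, ``slope``,
        ``quad``) to the tuple of covariate names entering its sub-model.
        The constant is always included implicitly and must not be listed.
    covariates : tuple of str
        Ordered covariate names, ``const`` first.
    """

    name: str
    shape: str
    inclusion: dict = field(default_factory=dict)
    covariates: tuple = ("const",)

    def __post_init__(self):
        if self.shape not in COEF_NAMES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.covariates[0] != "const":
            raise ValueError("covariates must start with 'const'")
        for coef, covs in self.inclusion.items():
            if coef not in self.coef_names:
                raise ValueError(f"unknown growth coefficient {coef!r}")
            unknown = set(covs) - set(self.covariates)
            if unknown:
                raise ValueError(f"covariates {sorted(unknown)} not declared")

    @property
    def coef_names(self) -> tuple:
        return COEF_NAMES[self.shape]

    @property
    def r(self) -> int:
        """Number of random growth coefficients (2 linear, 3 quadratic)."""
        return len(self.coef_names)

    @property
    def q(self) -> int:
        return len(self.covariates)

    def beta_mask(self) -> np.ndarray:
        """Boolean r x q mask of free entries of ``beta``.

        The constant column is always free; covariate columns follow the
        inclusion map.  Structural zeros are ``False``.
        """
        mask = np.zeros((self.r, self.q), dtype=bool)
        mask[:, 0] = True
        for m, coef in enumerate(self.coef_names):
            for cov in self.inclusion.get(coef, ()):
                mask[m, self.covariates.index(cov)] = True
        return mask

    @property
    def n_free_beta(self) -> int:
        return int(self.beta_mask().sum())

    def basis(self, t):
        """Evaluate ``f(t)``; vectorised over ``t``."""
        return basis_row(self, t)


def basis_row(spec: TrajectorySpec, t):
    """Polynomial basis ``f(t)``: ``(1, t)`` or ``(1, t, t^2)``.

    Accepts scalar or array ``t``; returns shape ``t.shape + (r,)``.
    """
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t), t]
    if spec.shape == "quadratic":
        cols.append(t * t)
    return np.stack(cols, axis=-1)


def beta_pattern(spec: TrajectorySpec, covariate_names=None) -> np.ndarray:
    """Free/structural-zero mask for ``beta`` (True = free).

    ``covariate_names``, if given, must equal the spec's declared covariates;
    this guards call sites that assemble the design independently.
    """
    if covariate_names is not None and tuple(covariate_names) != spec.covariates:
        raise ValueError(
            f"covariate order {tuple(covariate_names)} does not match spec "
            f"{spec.covariates}"
        )
    return spec.beta_mask()


def trajectory_value(b_i, spec: TrajectorySpec, t):
    """Latent trajectory value ``eta_i(t) = f(t)' b_i``."""
    b_i = np.asarray(b_i, dtype=float)
    if b_i.shape[-1] != spec.r:
        raise ValueError(f"b_i has length {b_i.shape[-1]}, spec needs r={spec.r}")
    return basis_row(spec, t) @ b_i


def fitted_mean_curve(growth, spec: TrajectorySpec, X, t_grid):
    """Population-mean trajectory ``f(t)' (beta X)`` for a covariate profile.

    ``X`` may be a single profile (length q) or a matrix of profiles; returns
    one curve per profile evaluated on ``t_grid``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.q:
        raise ValueError(f"profile length {X.shape[1]} != q={spec.q}")
    mean_b = X @ np.asarray(growth.beta).T  # (n_profiles, r)
    curves = basis_row(spec, np.asarray(t_grid, dtype=float)) @ mean_b.T
    return curves.T  # (n_profiles, len(t_grid))


def _preset(name, shape, slope=(), intercept=(), quad=()):
    inc = {}
    if intercept:
        inc["intercept"] = tuple(intercept)
    if slope:
        inc["slope"] = tuple(slope)
    if quad:
        inc["quad"] = tuple(quad)
    return TrajectorySpec(name=name, shape=shape, inclusion=inc, covariates=("const", "z"))


PRESETS = {
    "l_i": _preset("l_i", "linear", intercept=("z",)),
    "l_s": _preset("l_s", "linear", slope=("z",)),
    "l_is": _preset("l_is", "linear", intercept=("z",), slope=("z",)),
    "q_s": _preset("q_s", "quadratic", slope=("z",)),
    "q_sq": _preset("q_sq", "quadratic", slope=("z",), quad=("z",)),
}


def get_spec(name) -> TrajectorySpec:
    """Return a named preset, or pass a :class:`TrajectorySpec` through."""
    if isinstance(name, TrajectorySpec):
        return name
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown trajectory preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def covariate_extended_spec(covariates=("z", "bf", "kpsb", "stagele3", "agelt65",
                                        "gender", "race"),
                            exclude_from_intercept=("z", "bf")) -> TrajectorySpec:
    """Quadratic spec with arbitrary binary covariates in every sub-model.

    Treatment and pre-treatment supplementation are excluded from the
    intercept sub-model by default (the intercept is baseline status).
    """
    covs = tuple(covariates)
    inc = {
        "intercept": tuple(c for c in covs if c not in exclude_from_intercept),
        "slope": covs,
        "quad": covs,
    }
    return TrajectorySpec(name="q_cov", shape="quadratic", inclusion=inc,
                          covariates=("const",) + covs)
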
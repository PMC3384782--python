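"""Maximum-likelihood fitting of the joint models.

`JointModel` is built from the per-cycle longitudinal table and the survival
table, a trajectory specification and a link, and maximizes the marginal
joint likelihood (random effects integrated out by adaptive Gauss-Hermite
quadrature) over an unconstrained parameterization: free entries of ``beta``
on their natural scale, ``Sigma`` via its log-Cholesky factor, ``sigma`` and
the piecewise-constant baseline-hazard heights on the log scale, ``alpha``
and ``gamma`` natural.  ``fit()`` returns a `JointModelResults` carrying the
estimates, their covariance (inverse observed information), log-likelihood,
BIC and convergence diagnostics, with ``summary()``, Wald tests and effect
decomposition attached.

Model names follow the field convention: link prefix ``rem`` (shared random
effects) or ``traj`` (stepwise latent trajectory) plus the trajectory spec,
e.g. ``remq_s`` is the quadratic shape with treatment on the slope linked
through shared random effects.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import IntervalGrid, MarginalEngine, SubjectRecord
from .parameters import GrowthParameters, PiecewiseConstantHazard, SurvivalParameters
from .preprocess import apply_exclusions, cycle_average
from .separate import _fit_breslow
from .trajectories import TrajectorySpec, basis_row, fitted_mean_curve, get_spec

__all__ = ["JointModel", "JointModelResults", "ParameterPacker", "bic",
           "compare_models", "wald_joint_gamma", "observed_information"]

LINK_PREFIX = {"shared_re": "rem", "trajectory": "traj"}


def bic(logL: float, p: int, n: int) -> float:
    """Bayesian information criterion ``-2 log L + p log n``.

    ``n`` is the number of subjects (the likelihood is subject-indexed).
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    if n < 2:
        raise ValueError("n must be at least 2")
    return -2.0 * logL + p * np.log(n)


class ParameterPacker:
    """Bijection between named model parameters and the flat vector.

    Structural zeros of ``beta`` are simply absent from the vector, so no
    optimizer step can perturb them.
    """

    def __init__(self, spec: TrajectorySpec, link: str, alpha_names,
                 n_baseline: int, fix_gamma_zero: bool = False):
        self.spec = spec
        self.link = link
        self.alpha_names = tuple(alpha_names)
        self.n_baseline = int(n_baseline)
        self.fix_gamma_zero = bool(fix_gamma_zero)
        r = spec.r
        mask = spec.beta_mask()
        self.beta_idx = [(m, j) for m in range(r) for j in range(spec.q)
                         if mask[m, j]]
        names = [f"beta.{spec.coef_names[m]}.{spec.covariates[j]}"
                 for m, j in self.beta_idx]
        self.chol_idx = [(i, j) for i in range(r) for j in range(i + 1)]
        names += [f"logchol.{spec.coef_names[i]}.{spec.coef_names[j]}"
                  if i == j else f"chol.{spec.coef_names[i]}.{spec.coef_names[j]}"
                  for i, j in self.chol_idx]
        names += ["log_sigma"]
        names += [f"alpha.{a}" for a in self.alpha_names]
        if not fix_gamma_zero:
            if link == "shared_re":
                names += [f"gamma.{c}" for c in spec.coef_names]
            else:
                names += ["gamma"]
        names += [f"log_h{k}" for k in range(1, self.n_baseline + 1)]
        self.names = names
        self.n_gamma = 0 if fix_gamma_zero else (
            spec.r if link == "shared_re" else 1)

    @property
    def k(self) -> int:
        return len(self.names)

    def pack(self, growth: GrowthParameters, survival: SurvivalParameters):
        r = self.spec.r
        x = [growth.beta[m, j] for m, j in self.beta_idx]
        L = np.linalg.cholesky(growth.Sigma)
        for i, j in self.chol_idx:
            x.append(np.log(L[i, j]) if i == j else L[i, j])
        x.append(0.5 * np.log(growth.sigma2))
        x.extend(np.atleast_1d(survival.alpha))
        if not self.fix_gamma_zero:
            x.extend(np.atleast_1d(survival.gamma))
        x.extend(np.log(survival.baseline.heights))
        return np.asarray(x, float)

    def unpack(self, x):
        x = np.asarray(x, float)
        spec = self.spec
        r, q = spec.r, spec.q
        pos = 0
        beta = np.zeros((r, q))
        for m, j in self.beta_idx:
            beta[m, j] = x[pos]
            pos += 1
        L = np.zeros((r, r))
        for i, j in self.chol_idx:
            L[i, j] = np.exp(x[pos]) if i == j else x[pos]
            pos += 1
        Sigma = L @ L.T
        sigma2 = np.exp(2 * x[pos])
        pos += 1
        alpha = x[pos:pos + len(self.alpha_names)]
        pos += len(self.alpha_names)
        if self.fix_gamma_zero:
            gamma = np.zeros(r if self.link == "shared_re" else 1)
        else:
            gamma = x[pos:pos + self.n_gamma]
            pos += self.n_gamma
        heights = np.exp(x[pos:pos + self.n_baseline])
        return beta, Sigma, sigma2, alpha, gamma, heights


def _build_subjects(observations, survival, spec, alpha_names):
    surv = survival.set_index("subject_id", drop=False)
    need = set(spec.covariates[1:]) | (set(alpha_names) - {"const"})
    missing = need - set(survival.columns)
    if missing:
        raise ValueError(f"survival table lacks covariates {sorted(missing)}")
    obs_by = dict(tuple(observations.groupby("subject_id", sort=True))) \
        if len(observations) else {}
    subjects = []
    for sid, row in surv.iterrows():
        g = obs_by.get(sid)
        t = g["t"].to_numpy(float) if g is not None else np.empty(0)
        y = g["y"].to_numpy(float) if g is not None else np.empty(0)
        order = np.argsort(t)
        X = np.array([1.0] + [float(row[c]) for c in spec.covariates[1:]])
        Xs = np.array([1.0 if c == "const" else float(row[c])
                       for c in alpha_names])
        subjects.append(SubjectRecord(
            id=sid, X=X, X_s=Xs, t=t[order], y=y[order],
            T=float(row["time_months"]), delta=int(row["censored"])))
    return subjects


class JointModel:
    """Joint latent-growth / proportional-hazards model.

    Parameters
    ----------
    observations : DataFrame
        Per-cycle analysis dataset: ``subject_id, cycle, y, t`` (see
        :func:`jointlgm.preprocess.cycle_average`).
    survival : DataFrame
        ``subject_id, time_months, censored`` (1 censored, 0 event) plus
        covariate columns (``z`` and any others named by the spec).
    spec : str or TrajectorySpec
        Trajectory preset (``l_i, l_s, l_is, q_s, q_sq``) or a custom spec.
    link : {"shared_re", "trajectory"}
        How the hazard depends on the latent growth: linearly in the random
        coefficients, or through the stepwise trajectory value.
    grid : IntervalGrid, optional
        Survival-splitting grid for the trajectory link (default 0.7k).
    baseline_grid : {"cycle", "events"}
        Breakpoints of the piecewise-constant baseline hazard: the cycle
        grid (default; a handful of heights) or the unique event times
        (nonparametric flavour; many heights, much slower).
    quad_nodes : int
        Gauss-Hermite nodes per random-effect dimension.
    fix_gamma_zero : bool
        Constrain every link coefficient to zero (the model then factorizes
        into a mixed model and a piecewise-exponential survival model).
    """

    def __init__(self, observations, survival, spec="q_s", link="shared_re",
                 grid: IntervalGrid | None = None, baseline_grid="cycle",
                 quad_nodes: int = 9, survival_covariates=("z",),
                 fix_gamma_zero: bool = False):
        self.spec = get_spec(spec)
        if link not in LINK_PREFIX:
            raise ValueError(f"unknown link {link!r}")
        self.link = link
        self.grid = grid if grid is not None else IntervalGrid.cycles()
        self.survival_covariates = tuple(survival_covariates)
        self.observations = observations.reset_index(drop=True)
        self.survival = survival.reset_index(drop=True)
        self.subjects = _build_subjects(self.observations, self.survival,
                                        self.spec, self.survival_covariates)
        self.name = LINK_PREFIX[link] + self.spec.name

        T = self.survival["time_months"].to_numpy(float)
        delta = self.survival["censored"].to_numpy(int)
        if baseline_grid == "cycle":
            breaks = self.grid.breaks
        elif baseline_grid == "events":
            ev = np.unique(T[delta == 0])
            if ev.size < 2:
                raise ValueError("need at least 2 distinct event times for "
                                 "the event-time baseline grid")
            breaks = ev[:-1]
        else:
            raise ValueError("baseline_grid must be 'cycle' or 'events'")
        self.baseline_breaks = np.asarray(breaks, float)
        self.packer = ParameterPacker(self.spec, link,
                                      self.survival_covariates,
                                      len(self.baseline_breaks) + 1,
                                      fix_gamma_zero=fix_gamma_zero)
        self.engine = MarginalEngine(self.subjects, self.spec, link,
                                     grid=self.grid,
                                     baseline_breaks=self.baseline_breaks,
                                     quad_nodes=quad_nodes)
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(
            self.observations[["subject_id", "cycle", "y", "t"]]
            .to_numpy(float)).tobytes())
        h.update(np.ascontiguousarray(
            self.survival.select_dtypes("number").to_numpy(float)).tobytes())
        self.data_hash = h.hexdigest()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort, item=None, days_per_month=30.0, **kwargs):
        """Build from a simulated :class:`~jointlgm.simulate.CohortData`."""
        obs = cycle_average(cohort.longitudinal, item=item,
                            days_per_month=days_per_month)
        obs, _ = apply_exclusions(obs, cohort.survival)
        return cls(obs, cohort.survival, **kwargs)

    @classmethod
    def from_csv(cls, longitudinal_path, survival_path, item=None,
                 days_per_month=30.0, **kwargs):
        """Build from the longitudinal/survival CSV files."""
        long_df = pd.read_csv(longitudinal_path)
        surv_df = pd.read_csv(survival_path)
        obs = cycle_average(long_df, item=item, days_per_month=days_per_month)
        obs, _ = apply_exclusions(obs, surv_df)
        return cls(obs, surv_df, **kwargs)

    # -- likelihood ---------------------------------------------------------

    @property
    def nobs(self) -> int:
        return len(self.subjects)

    def loglike(self, params) -> float:
        """Marginal joint log-likelihood at a packed parameter vector."""
        beta, Sigma, sigma2, alpha, gamma, heights = self.packer.unpack(params)
        return self.engine.loglik(beta, Sigma, sigma2, alpha, gamma, heights)

    def initialize(self) -> np.ndarray:
        """Deterministic starting values.

        Growth parameters from two-stage per-subject least squares plus
        moments; ``alpha`` from a Breslow Cox fit on the survival
        covariates; ``gamma = 0``; baseline heights from per-interval
        occurrence/exposure rates.
        """
        spec = self.spec
        r = spec.r
        usable = [s for s in self.subjects if len(s.y) >= r]
        if not usable:
            raise ValueError("no subject has enough observations "
                             f"(need at least r={r}) to initialize")
        bhat, Xrows, rss, dof = [], [], 0.0, 0
        for s in usable:
            F = basis_row(spec, s.t)
            coef, res, rank, _ = np.linalg.lstsq(F, s.y, rcond=None)
            bhat.append(coef)
            Xrows.append(s.X)
            if len(s.y) > r and rank == r:
                rss += float(res[0]) if res.size else 0.0
                dof += len(s.y) - r
        bhat = np.array(bhat)
        Xmat = np.array(Xrows)
        sigma2 = rss / dof if dof > 0 else max(np.var(
            np.concatenate([s.y for s in usable])) / 4.0, 1.0)
        mask = spec.beta_mask()
        beta = np.zeros((r, spec.q))
        for m in range(r):
            cols = np.where(mask[m])[0]
            coef, *_ = np.linalg.lstsq(Xmat[:, cols], bhat[:, m], rcond=None)
            beta[m, cols] = coef
        resid = bhat - Xmat @ beta.T
        Sigma = np.cov(resid.T) if len(usable) > r else np.eye(r)
        Sigma = np.atleast_2d(Sigma)
        w, V = np.linalg.eigh(Sigma)
        floor = max(1e-3, 1e-3 * float(np.trace(Sigma)) / r)
        Sigma = (V * np.maximum(w, floor)) @ V.T

        Xs = np.array([s.X_s for s in self.subjects])
        T = np.array([s.T for s in self.subjects])
        event = np.array([s.delta for s in self.subjects]) == 0
        try:
            cox = _fit_breslow(Xs, np.zeros(len(T)), T, event,
                               names=list(self.survival_covariates))
            alpha = cox.coef.to_numpy()
        except ValueError:
            alpha = np.zeros(len(self.survival_covariates))
        events_per_piece = np.bincount(self.engine.piece_T[event],
                                       minlength=self.engine.n_baseline)
        exposure = self.engine.expo_base.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            heights = events_per_piece / exposure
        pos = heights[np.isfinite(heights) & (heights > 0)]
        fallback = float(pos.min()) / 2 if pos.size else 0.01
        heights = np.where(np.isfinite(heights) & (heights > 0), heights,
                           fallback)
        gamma = np.zeros(r) if self.link == "shared_re" else np.zeros(1)
        growth = GrowthParameters(beta, Sigma, sigma2)
        growth.beta[~mask] = 0.0
        surv = SurvivalParameters(
            alpha=alpha, gamma=gamma,
            baseline=PiecewiseConstantHazard(self.baseline_breaks, heights),
            alpha_names=self.survival_covariates)
        return self.packer.pack(growth, surv)

    def fit(self, start_params=None, maxiter=200, gtol=1e-5,
            compute_se=True) -> "JointModelResults":
        """Quasi-Newton maximization of the marginal log-likelihood."""
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self.initialize()
        trace = []

        def neg(x):
            v = self.loglike(x)
            trace.append(v)
            return -v if np.isfinite(v) else 1e12

        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
        llf = float(-res.fun)
        grad_norm = float(np.max(np.abs(res.jac)))
        # the achievable gradient norm is limited by finite-difference noise,
        # which scales with |log L|; accept stationarity relative to it
        converged = bool(res.success) or grad_norm < 1e-4 * (1.0 + abs(llf))
        if not converged:
            warnings.warn(
                f"joint-model optimization did not converge "
                f"(gradient max-norm {grad_norm:.2e}); partial results "
                "retained", RuntimeWarning)
        cov = None
        if compute_se:
            cov = observed_information(self, res.x)
        return JointModelResults(self, res.x, llf, cov, converged, grad_norm,
                                 nit=int(res.nit), trace=trace)


def observed_information(model: JointModel, params, rel_step=1e-4):
    """Covariance of the estimates from the observed information.

    Central-difference Hessian of the log-likelihood at the estimate,
    negated and inverted (pseudo-inverse with a warning if the information
    matrix is not positive definite).
    """
    x = np.asarray(params, float)
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    f0 = model.loglike(x)
    H = np.zeros((k, k))

    def f(dx):
        return model.loglike(x + dx)

    fp = np.zeros(k)
    fm = np.zeros(k)
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        fp[j] = f(e)
        fm[j] = f(-e)
        H[j, j] = (fp[j] - 2 * f0 + fm[j]) / h[j] ** 2
    for j in range(k):
        for l in range(j + 1, k):
            e = np.zeros(k)
            e[j], e[l] = h[j], h[l]
            fpp = f(e)
            e[l] = -h[l]
            fpm = f(e)
            e[j], e[l] = -h[j], h[l]
            fmp = f(e)
            e[l] = -h[l]
            fmm = f(e)
            H[j, l] = H[l, j] = (fpp - fpm - fmp + fmm) / (4 * h[j] * h[l])
    info = -H
    info = 0.5 * (info + info.T)
    try:
        L = np.linalg.cholesky(info)
        Linv = np.linalg.inv(L)
        cov = Linv.T @ Linv
    except np.linalg.LinAlgError:
        warnings.warn("observed information is not positive definite; "
                      "using the pseudo-inverse", RuntimeWarning)
        cov = np.linalg.pinv(info)
    return 0.5 * (cov + cov.T)


class JointModelResults:
    """Estimates, uncertainty and diagnostics of a joint-model fit."""

    def __init__(self, model: JointModel, params, llf, cov_params, converged,
                 grad_norm, nit=0, trace=None):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = float(llf)
        self.cov_params = cov_params
        self.converged = converged
        self.grad_norm = grad_norm
        self.nit = nit
        self.trace = trace if trace is not None else []

    # -- bookkeeping --------------------------------------------------------

    @property
    def name(self):
        return self.model.name

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_model(self) -> int:
        return self.model.packer.k

    @property
    def bic(self) -> float:
        return bic(self.llf, self.df_model, self.nobs)

    @property
    def params_named(self) -> pd.Series:
        return pd.Series(self.params, index=self.model.packer.names)

    @property
    def bse(self) -> pd.Series:
        if self.cov_params is None:
            return pd.Series(np.nan, index=self.model.packer.names)
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov_params), 0, None)),
                         index=self.model.packer.names)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params_named / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)),
                         index=self.model.packer.names)

    # -- reconstructed parameter objects ------------------------------------

    def _unpacked(self):
        return self.model.packer.unpack(self.params)

    @property
    def growth_params(self) -> GrowthParameters:
        beta, Sigma, sigma2, *_ = self._unpacked()
        return GrowthParameters(beta, Sigma, sigma2)

    @property
    def survival_params(self) -> SurvivalParameters:
        *_, alpha, gamma, heights = self._unpacked()
        return SurvivalParameters(
            alpha=alpha, gamma=gamma,
            baseline=PiecewiseConstantHazard(self.model.baseline_breaks,
                                             heights),
            alpha_names=self.model.survival_covariates)

    def fitted_mean_curve(self, t_grid, profiles=None):
        """Population-mean trajectories per arm (or given covariate profiles)."""
        spec = self.model.spec
        if profiles is None:
            profiles = np.zeros((2, spec.q))
            profiles[:, 0] = 1.0
            if "z" in spec.covariates:
                profiles[1, spec.covariates.index("z")] = 1.0
        return fitted_mean_curve(self.growth_params, spec, profiles, t_grid)

    # -- inference ----------------------------------------------------------

    def wald_gamma(self):
        return wald_joint_gamma(self)

    def decompose(self, covariate="z"):
        from .effects import decompose
        return decompose(self, covariate)

    def to_json(self, path=None):
        """Serialize the fit (named estimates, llf, BIC, diagnostics)."""
        out = {
            "model": self.name,
            "params": {k: float(v) for k, v in self.params_named.items()},
            "bse": {k: (None if np.isnan(v) else float(v))
                    for k, v in self.bse.items()},
            "llf": self.llf, "bic": float(self.bic), "n": self.nobs,
            "p": self.df_model, "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "quad_nodes": self.model.engine.quad_nodes,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=2)
        return out

    def _stars(self, p):
        return "**" if p < 0.01 else "*" if p < 0.05 else ""

    def summary(self) -> str:
        lines = [
            f"Joint model {self.name} ({self.model.link} link)",
            f"subjects: {self.nobs}   events: "
            f"{int((self.model.survival['censored'] == 0).sum())}   "
            f"free parameters: {self.df_model}",
            f"log-likelihood: {self.llf:.3f}   BIC: {self.bic:.2f}   "
            f"converged: {self.converged}",
            "",
            f"{'parameter':<28}{'estimate':>10}{'SE':>9}{'p':>11}",
        ]
        bse = self.bse
        pv = self.pvalues
        for nm, val in self.params_named.items():
            se = bse[nm]
            p = pv[nm]
            star = "" if np.isnan(p) else self._stars(p)
            lines.append(f"{nm:<28}{val:>10.4f}"
                         + (f"{se:>9.4f}{p:>11.3g} {star}" if np.isfinite(se)
                            else f"{'-':>9}{'-':>11}"))
        try:
            dec = self.decompose("z")
            lines += ["", f"direct treatment HR: {dec.hr_direct:.3f}   "
                          f"overall treatment HR: {dec.hr_overall:.3f}"]
        except (KeyError, ValueError):
            pass
        return "\n".join(lines)

    def __repr__(self):
        return (f"<JointModelResults {self.name}: llf={self.llf:.2f}, "
                f"BIC={self.bic:.2f}, converged={self.converged}>")


def wald_joint_gamma(results: JointModelResults):
    """Wald test of the joint null that every link coefficient is zero.

    Returns ``(statistic, df, p)`` with the statistic
    ``gamma' V_gamma^{-1} gamma`` referred to chi-square with
    ``df = dim(gamma)``.
    """
    names = [nm for nm in results.model.packer.names
             if nm == "gamma" or nm.startswith("gamma.")]
    if not names:
        raise ValueError("model has no free link coefficients")
    if results.cov_params is None:
        raise ValueError("fit has no covariance; refit with compute_se=True")
    idx = [results.model.packer.names.index(nm) for nm in names]
    g = results.params[idx]
    V = results.cov_params[np.ix_(idx, idx)]
    try:
        stat = float(g @ np.linalg.solve(V, g))
    except np.linalg.LinAlgError:
        raise ValueError("singular covariance of the link coefficients")
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


RAFTERY = [(2.0, "weak"), (6.0, "positive"), (10.0, "strong"),
           (np.inf, "very strong")]


def raftery_grade(diff: float) -> str:
    """Evidence grade for a BIC difference (0-2 weak, 2-6 positive,
    6-10 strong, >10 very strong)."""
    for hi, grade in RAFTERY:
        if diff <= hi:
            return grade
    raise AssertionError  # pragma: no cover


def compare_models(results_list) -> pd.DataFrame:
    """BIC comparison table across fits of the same dataset.

    Rows sorted by BIC; differences are relative to the best (smallest-BIC)
    model, with Raftery evidence grades.  Fits of different datasets are
    rejected by checksum.
    """
    if not results_list:
        raise ValueError("no fits to compare")
    hashes = {r.model.data_hash for r in results_list}
    if len(hashes) > 1:
        raise ValueError("fits were made on different datasets "
                         "(data checksums differ)")
    rows = sorted(((r.name, r.bic, r.llf, r.df_model) for r in results_list),
                  key=lambda t: t[1])
    best = rows[0][1]
    return pd.DataFrame(
        [(nm, b, b - best, raftery_grade(b - best), llf, p)
         for nm, b, llf, p in rows],
        columns=["model", "bic", "delta_bic", "evidence", "llf", "p"])
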
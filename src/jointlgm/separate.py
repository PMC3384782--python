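"""Conventional separate and naive combined analyses.

Three comparators for the joint model:

* an MMRM (mixed-effects model for repeated measures) on the cycle-mean
  scores with treatment, cycle (categorical) and their interaction as fixed
  effects and a compound-symmetry or AR(1) within-subject covariance,
  estimated by maximum likelihood so BICs are comparable;
* a Cox proportional-hazards model with treatment as the only covariate;
* the naive time-varying-covariate Cox model, in which the observed
  cycle-mean score enters the hazard directly (last observation carried
  forward between assessments).  This ignores measurement error and is
  expected to attenuate the association toward the null.

Cox partial likelihoods use the Breslow tie convention throughout, on a
counting-process episode table; a subject enters the risk set at its first
assessment in the time-varying model (delayed entry) rather than having a
value imputed before any assessment exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MMRMResult",
    "CoxResult",
    "fit_mmrm",
    "lsmean_difference",
    "fit_cox_treatment",
    "build_counting_process",
    "fit_naive_tv_cox",
]


# ---------------------------------------------------------------------------
# MMRM
# ---------------------------------------------------------------------------

@dataclass
class MMRMResult:
    """ML fit of the cell-means MMRM with CS or AR(1) covariance."""

    covariance_kind: str
    cell_means: pd.Series           # indexed by (z, cycle)
    cov_cell_means: np.ndarray
    sigma2: float
    rho: float
    llf: float
    bic: float
    n_subjects: int
    p: int
    converged: bool
    cycles: tuple = field(default=())

    def lsmeans(self, cycle: int) -> pd.DataFrame:
        """Model-implied (least-squares) means per arm at a cycle, with SE."""
        rows = []
        idx = list(self.cell_means.index)
        for z in (0, 1):
            j = idx.index((z, cycle))
            rows.append((z, self.cell_means.iloc[j],
                         np.sqrt(self.cov_cell_means[j, j])))
        return pd.DataFrame(rows, columns=["z", "lsmean", "se"])


def _subject_blocks(observations: pd.DataFrame):
    blocks = []
    for sid, gdf in observations.groupby("subject_id", sort=True):
        gdf = gdf.sort_values("cycle")
        blocks.append((int(gdf["z"].iloc[0]), gdf["cycle"].to_numpy(int),
                       gdf["y"].to_numpy(float)))
    return blocks


def _corr(kind, cycles, rho):
    if kind == "AR1":
        lag = np.abs(cycles[:, None] - cycles[None, :])
        return rho ** lag
    if kind == "CS":
        m = np.full((len(cycles), len(cycles)), rho)
        np.fill_diagonal(m, 1.0)
        return m
    raise ValueError(f"unknown covariance kind {kind!r}")


def _mmrm_profiled(blocks, design_index, kind, sigma2, rho):
    """Profiled GLS: returns (llf, beta_hat, cov_beta)."""
    ncell = len(design_index)
    XtVX = np.zeros((ncell, ncell))
    XtVy = np.zeros(ncell)
    quad = 0.0
    logdet = 0.0
    ntot = 0
    pos = {key: j for j, key in enumerate(design_index)}
    cached = []
    for z, cycles, y in blocks:
        V = sigma2 * _corr(kind, cycles, rho)
        Vi = np.linalg.inv(V)
        cols = [pos[(z, int(c))] for c in cycles]
        cached.append((cols, Vi, y, V))
        XtVX[np.ix_(cols, cols)] += Vi
        XtVy[cols] += Vi @ y
        sign, ld = np.linalg.slogdet(V)
        logdet += ld
        ntot += len(y)
    beta = np.linalg.solve(XtVX, XtVy)
    for cols, Vi, y, V in cached:
        r = y - beta[cols]
        quad += r @ Vi @ r
    llf = -0.5 * (ntot * np.log(2 * np.pi) + logdet + quad)
    return llf, beta, np.linalg.inv(XtVX)


def fit_mmrm(observations: pd.DataFrame, covariance_kind: str = "AR1",
             survival: pd.DataFrame | None = None,
             max_cycle: int = 6) -> MMRMResult:
    """Fit the MMRM by direct Gaussian maximum likelihood.

    ``observations`` needs columns ``subject_id, cycle, y`` and a treatment
    column ``z`` (merged from ``survival`` if absent).  The mean structure
    is saturated in (arm x cycle) cells, equivalent to treatment + cycle +
    interaction; the within-subject covariance is ``sigma^2`` times a CS or
    AR(1) correlation in cycle lag.  BIC uses the number of subjects as the
    sample size in the penalty.
    """
    obs = observations
    if "z" not in obs.columns:
        if survival is None:
            raise ValueError("observations lack 'z'; pass the survival table")
        obs = obs.merge(survival[["subject_id", "z"]], on="subject_id")
    obs = obs[obs["cycle"] <= max_cycle]
    blocks = _subject_blocks(obs)
    if sum(z == 0 for z, *_ in blocks) < 2 or sum(z == 1 for z, *_ in blocks) < 2:
        raise ValueError("need at least 2 subjects per arm")
    cycles_present = sorted(obs["cycle"].unique())
    design_index = [(z, int(c)) for z in (0, 1) for c in cycles_present]

    if covariance_kind == "AR1":
        lo, hi = -0.999, 0.999
    else:
        mmax = max(len(y) for _, _, y in blocks)
        lo, hi = (-1.0 / (mmax - 1) + 1e-6) if mmax > 1 else -0.5, 0.999

    var0 = float(np.var(obs["y"])) or 1.0

    def unpack(x):
        sigma2 = np.exp(x[0])
        rho = lo + (hi - lo) / (1.0 + np.exp(-x[1]))
        return sigma2, rho

    def nll(x):
        sigma2, rho = unpack(x)
        try:
            llf, _, _ = _mmrm_profiled(blocks, design_index, covariance_kind,
                                       sigma2, rho)
        except np.linalg.LinAlgError:
            return np.inf
        return -llf

    res = optimize.minimize(nll, x0=np.array([np.log(var0), 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 2000})
    if not res.success:
        warnings.warn(f"MMRM variance optimization did not converge: "
                      f"{res.message}", RuntimeWarning)
    sigma2, rho = unpack(res.x)
    llf, beta, cov_beta = _mmrm_profiled(blocks, design_index,
                                         covariance_kind, sigma2, rho)
    n = len(blocks)
    p = len(design_index) + 2
    return MMRMResult(
        covariance_kind=covariance_kind,
        cell_means=pd.Series(beta, index=pd.MultiIndex.from_tuples(
            design_index, names=["z", "cycle"])),
        cov_cell_means=cov_beta, sigma2=sigma2, rho=rho, llf=float(llf),
        bic=float(-2 * llf + p * np.log(n)), n_subjects=n, p=p,
        converged=bool(res.success), cycles=tuple(cycles_present))


def lsmean_difference(result: MMRMResult, cycle: int) -> dict:
    """Arm difference in LSMeans at a cycle, with delta-method SE and p."""
    ls = result.lsmeans(cycle)
    idx = list(result.cell_means.index)
    j0, j1 = idx.index((0, cycle)), idx.index((1, cycle))
    diff = result.cell_means.iloc[j1] - result.cell_means.iloc[j0]
    var = (result.cov_cell_means[j1, j1] + result.cov_cell_means[j0, j0]
           - 2 * result.cov_cell_means[j1, j0])
    se = float(np.sqrt(var))
    zstat = diff / se if se > 0 else np.inf
    return {"lsmeans": ls, "difference": float(diff), "se": se,
            "p_value": float(2 * stats.norm.sf(abs(zstat)))}


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties) on counting-process episodes
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Breslow partial-likelihood fit."""

    coef: pd.Series
    se: pd.Series
    hazard_ratios: pd.Series
    loglik: float
    p_values: pd.Series
    converged: bool
    monotone_flag: bool = False
    extras: dict = field(default_factory=dict)


def _breslow_parts(beta, X, start, stop, event):
    """Breslow partial log-likelihood with analytic gradient and Hessian."""
    lp = X @ beta
    elp = np.exp(np.minimum(lp, 700.0))
    ll, grad = 0.0, np.zeros(len(beta))
    hess = np.zeros((len(beta), len(beta)))
    for e in np.unique(stop[event]):
        cases = event & (stop == e)
        risk = (start < e) & (e <= stop)
        d = int(cases.sum())
        s0 = elp[risk].sum()
        s1 = X[risk].T @ elp[risk]
        s2 = (X[risk] * elp[risk, None]).T @ X[risk]
        ll += lp[cases].sum() - d * np.log(s0)
        grad += X[cases].sum(axis=0) - d * s1 / s0
        hess -= d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
    return ll, grad, hess


def _fit_breslow(X, start, stop, event, names, cap=15.0):
    if event.sum() == 0:
        raise ValueError("no events in the data; Cox model undefined")
    beta = np.zeros(X.shape[1])
    monotone = False
    for _ in range(200):
        ll, grad, hess = _breslow_parts(beta, X, start, stop, event)
        if np.max(np.abs(grad)) < 1e-12:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = -grad
        if np.max(np.abs(step)) > 5:
            step = step * 5 / np.max(np.abs(step))
        beta_new = beta + step
        if np.max(np.abs(beta_new)) > cap:
            monotone = True
            beta_new = np.clip(beta_new, -cap, cap)
        if np.max(np.abs(beta_new - beta)) < 1e-14:
            beta = beta_new
            break
        beta = beta_new
    ll, grad, hess = _breslow_parts(beta, X, start, stop, event)
    converged = np.max(np.abs(grad)) < 1e-6 or monotone
    if monotone:
        warnings.warn("monotone partial likelihood: coefficient capped at "
                      f"+/-{cap}", RuntimeWarning)
    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.full_like(beta, np.inf), where=se > 0)
    return CoxResult(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        hazard_ratios=pd.Series(np.exp(beta), index=names),
        loglik=float(ll),
        p_values=pd.Series(2 * stats.norm.sf(np.abs(z)), index=names),
        converged=bool(converged), monotone_flag=monotone)


def fit_cox_treatment(survival: pd.DataFrame) -> CoxResult:
    """Cox model with treatment as the only covariate (Breslow ties).

    ``survival`` columns: ``subject_id, time_months, censored`` (1 censored,
    0 event) and ``z``.
    """
    event = survival["censored"].to_numpy(int) == 0
    for arm in (0, 1):
        if event[survival["z"].to_numpy(int) == arm].sum() == 0:
            warnings.warn(f"no events in arm z={arm}: the partial likelihood "
                          "is monotone in the treatment coefficient",
                          RuntimeWarning)
    X = survival[["z"]].to_numpy(float)
    start = np.zeros(len(survival))
    stop = survival["time_months"].to_numpy(float)
    return _fit_breslow(X, start, stop, event, names=["z"])


def build_counting_process(observations: pd.DataFrame,
                           survival: pd.DataFrame) -> pd.DataFrame:
    """Episode table for the time-varying-covariate Cox model.

    Each subject contributes episodes ``[t_j, t_{j+1})`` carrying the most
    recent cycle-mean score (LOCF), the last ending at the observed time
    with the subject's event status.  Subjects enter the risk set at their
    first assessment (delayed entry); subjects with no assessment strictly
    before their observed time are dropped, with the count recorded in
    ``episodes.attrs['n_dropped']``.
    """
    surv = survival.set_index("subject_id")
    orphans = sorted(set(observations["subject_id"]) - set(surv.index))
    if orphans:
        raise KeyError(f"observations without survival record: {orphans}")
    extra_covs = [c for c in survival.columns
                  if c not in ("subject_id", "time_months", "censored")]
    rows, n_dropped = [], 0
    for sid in surv.index:
        T = float(surv.loc[sid, "time_months"])
        ev = int(surv.loc[sid, "censored"]) == 0
        sub = observations[observations["subject_id"] == sid].sort_values("t")
        times = sub.loc[sub["t"] < T, "t"].to_numpy(float)
        values = sub.loc[sub["t"] < T, "y"].to_numpy(float)
        if times.size == 0:
            n_dropped += 1
            continue
        edges = np.concatenate([times, [T]])
        covvals = [surv.loc[sid, c] for c in extra_covs]
        for j in range(len(times)):
            rows.append((sid, edges[j], edges[j + 1],
                         int(ev and j == len(times) - 1), values[j], *covvals))
    episodes = pd.DataFrame(
        rows, columns=["subject_id", "start", "stop", "event", "value",
                       *extra_covs])
    episodes.attrs["n_dropped"] = n_dropped
    return episodes


def fit_naive_tv_cox(episodes: pd.DataFrame,
                     covariates=("z", "value")) -> CoxResult:
    """Naive Cox model with the observed score as a time-varying covariate.

    Reports the per-point hazard ratio for the score and the percent hazard
    increase per 10 points, ``100 (e^{10 gamma} - 1)``.
    """
    event = episodes["event"].to_numpy(bool)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    X = episodes[list(covariates)].to_numpy(float)
    res = _fit_breslow(X, episodes["start"].to_numpy(float),
                       episodes["stop"].to_numpy(float), event,
                       names=list(covariates))
    gam = float(res.coef["value"])
    res.extras["hr_per_point"] = float(np.exp(gam))
    res.extras["pct_per_10_points"] = float(100 * (np.exp(10 * gam) - 1))
    return res
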
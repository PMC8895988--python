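"""Plot-level mixed model: REML variance components, BLUEs, heritability.

The model for a multi-environment trial is

    y_ijkl = mu + g_i + e_j + (ge)_ij + r_jk + b_jkl + eps_ijkl

with genotype g, environment e (location-year combination), their
interaction, replicate nested in environment, incomplete block nested in
replicate, and a homogeneous-variance residual.  All design factors are
random; genotype is random when variance components and broad-sense
heritability are wanted and fixed when best linear unbiased estimates
(BLUEs) of the genotype means are wanted.

REML is computed through the mixed-model equations.  With the residual
variance profiled out and gamma_f = sigma2_f / sigma2_eps, minus twice the
restricted log-likelihood is, up to a constant,

    F(gamma) = (n - p) log(y'Py) + log|C| + sum_f q_f log gamma_f

where C is the mixed-model coefficient matrix built with R = I and
G^-1 = diag(1/gamma_f).  F is minimised over log gamma; small problems use
a dense Cholesky with analytic gradients, large ones a sparse LU with
Nelder-Mead.  Components driven to the lower boundary are fixed at zero and
the remaining ones re-optimised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConvergenceError,
    DesignError,
    UndefinedStatisticError,
)

__all__ = [
    "VarianceComponents",
    "ModelFit",
    "fit_plot_model",
    "fit_plot_model_multi",
    "heritability",
    "group_heritabilities",
    "compute_blues",
    "detect_outliers",
]

#: plot-table key columns expected by every operation here
KEY_COLUMNS = ("genotype", "environment", "replicate", "block")

_GAMMA_FLOOR = 1e-7  # gamma below this is treated as a zero component
_LOG_BOUNDS = (np.log(1e-8), np.log(1e8))
_DENSE_LIMIT = 900  # MME dimension up to which the dense path is used


@dataclass
class VarianceComponents:
    """REML variance components of the plot model, in trait units squared.

    ``None`` marks a component that the design cannot separate (for example
    genotype-by-environment with a single environment).
    """

    sigma2_g: float | None
    sigma2_gxe: float | None
    sigma2_env: float | None
    sigma2_rep: float | None
    sigma2_block: float | None
    sigma2_eps: float
    ne: int
    nr: float

    def as_dict(self) -> dict:
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_gxe": self.sigma2_gxe,
            "sigma2_env": self.sigma2_env,
            "sigma2_rep": self.sigma2_rep,
            "sigma2_block": self.sigma2_block,
            "sigma2_eps": self.sigma2_eps,
        }


@dataclass
class ModelFit:
    """Result of one REML fit of the plot model."""

    mode: str  # "all-random" | "genotype-fixed"
    mu: float
    vc: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    blues: pd.Series | None = None  # genotype-fixed mode only
    genotype_effects: pd.Series | None = None  # BLUPs, all-random mode
    gamma: dict = field(default_factory=dict)  # variance ratios, for warm starts
    trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# design construction


def _require_columns(plots: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLUMNS if c not in plots.columns]
    if missing:
        raise DesignError(f"plot table lacks required columns: {missing}")


def _factor_matrix(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.shape[0]
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _build_design(plots: pd.DataFrame, trait: str, genotype_fixed: bool):
    """Assemble y, fixed X and the random-factor incidence matrices.

    Factors that the design cannot support (single environment, a single
    replicate everywhere, one block per replicate, or a factor with one
    observation per level that would be confounded with the residual) are
    dropped; the caller sees which survived via the returned dict.
    """
    _require_columns(plots)
    obs = plots[plots[trait].notna()].reset_index(drop=True)
    if len(obs) == 0:
        raise DesignError(f"no non-missing observations for trait {trait!r}")
    y = obs[trait].to_numpy(dtype=float)
    n = len(obs)

    geno_codes, geno_levels = pd.factorize(obs["genotype"], sort=True)
    env_codes, env_levels = pd.factorize(obs["environment"], sort=True)
    n_geno, n_env = len(geno_levels), len(env_levels)
    if n_geno < 2:
        raise DesignError("need at least 2 genotypes")

    if genotype_fixed:
        X = _factor_matrix(geno_codes, n_geno)  # cell-means coding: BLUEs
    else:
        X = sp.csr_matrix(np.ones((n, 1)))

    Z: dict[str, sp.csr_matrix] = {}
    if not genotype_fixed:
        Z["genotype"] = _factor_matrix(geno_codes, n_geno)
    rep_vals = obs["replicate"].to_numpy(dtype=np.int64)
    blk_vals = obs["block"].to_numpy(dtype=np.int64)
    if n_env >= 2:
        Z["env"] = _factor_matrix(env_codes, n_env)
        ge_codes, ge_levels = pd.factorize(
            geno_codes.astype(np.int64) * n_env + env_codes, sort=True
        )
        # one observation per g-x-e cell would be confounded with the residual
        if len(ge_levels) < n:
            Z["gxe"] = _factor_matrix(ge_codes, len(ge_levels))
    rep_codes, rep_levels = pd.factorize(
        env_codes.astype(np.int64) * (rep_vals.max() + 1) + rep_vals, sort=True
    )
    if len(rep_levels) > n_env and len(rep_levels) < n:
        Z["rep"] = _factor_matrix(rep_codes, len(rep_levels))
    blk_codes, blk_levels = pd.factorize(
        rep_codes.astype(np.int64) * (blk_vals.max() + 1) + blk_vals, sort=True
    )
    if len(blk_levels) > len(rep_levels) and len(blk_levels) < n:
        Z["block"] = _factor_matrix(blk_codes, len(blk_levels))

    meta = {
        "genotype_levels": geno_levels,
        "env_levels": env_levels,
        "n_env": n_env,
        "obs": obs,
    }
    return y, X, Z, meta


# ---------------------------------------------------------------------------
# REML engine


def _chol_inverse(cf):
    """Inverse of a matrix from its Cholesky factor (LAPACK potri)."""
    c, lower = cf
    inv, info = sla.lapack.dpotri(c, lower=lower)
    if info != 0:
        raise sla.LinAlgError(f"dpotri failed with info={info}")
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


class _REMLProblem:
    """Profiled REML objective via the mixed-model equations.

    The coefficient matrix block of any single factor is diagonal, so when
    the full system exceeds the dense limit the factor with the most
    levels (typically genotype-by-environment) is absorbed by its Schur
    complement, leaving a small dense system whose Cholesky gives the
    objective and whose inverse gives analytic gradients.
    """

    def __init__(self, y, X, Z: dict):
        self.names = list(Z)
        self.p = X.shape[1]
        self.q = [Z[f].shape[1] for f in self.names]
        self.n = y.shape[0]
        self.dim = self.p + sum(self.q)

        self.absorb = None
        if self.dim > _DENSE_LIMIT and self.names:
            i_max = int(np.argmax(self.q))
            if self.dim - self.q[i_max] < self.dim:
                self.absorb = self.names[i_max]
        part1 = [f for f in self.names if f != self.absorb]
        self.part1 = part1

        A1 = sp.hstack([X] + [Z[f] for f in part1], format="csc")
        self.A1 = A1
        self.d1 = A1.shape[1]
        self.M11 = (A1.T @ A1).toarray()
        # slices of each part-1 factor inside the reduced system
        self.slices = {}
        start = self.p
        for f in part1:
            q = Z[f].shape[1]
            self.slices[f] = slice(start, start + q)
            start += q
        self.Za = Z[self.absorb].tocsc() if self.absorb is not None else None
        if self.Za is not None:
            self.M1a = (A1.T @ self.Za).tocsc()
            self.M1a_dense = None  # built lazily for gradient evals
            self.diag_a = np.asarray(self.Za.multiply(self.Za).sum(axis=0)).ravel()
            self.qa = self.Za.shape[1]
        self.set_response(y)

    def set_response(self, y) -> None:
        """Swap in a new response on the same design (multi-response fits)."""
        self.yty = float(y @ y)
        self.b1 = np.asarray(self.A1.T @ y).ravel()
        if self.Za is not None:
            self.ba = np.asarray(self.Za.T @ y).ravel()

    def _penalty1(self, gamma: dict) -> np.ndarray:
        d = np.zeros(self.d1)
        for f in self.part1:
            sl = self.slices[f]
            d[sl.start : sl.stop] = 1.0 / gamma[f]
        return d

    def _assemble(self, gamma: dict):
        d1 = self._penalty1(gamma)
        if self.absorb is None:
            S = self.M11 + np.diag(d1)
            return S, None, self.b1, None
        Da = self.diag_a + 1.0 / gamma[self.absorb]
        Srem = (self.M1a.multiply(1.0 / Da) @ self.M1a.T).toarray()
        S = self.M11 + np.diag(d1) - Srem
        rhs1 = self.b1 - self.M1a @ (self.ba / Da)
        return S, Da, rhs1, None

    def objective(self, theta, want_grad=False):
        gamma = {f: g for f, g in zip(self.names, np.exp(theta))}
        nmp = self.n - self.p
        S, Da, rhs1, _ = self._assemble(gamma)
        try:
            cf = sla.cho_factor(S, lower=True, check_finite=False)
        except sla.LinAlgError:
            return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        if Da is not None:
            logdet += float(np.sum(np.log(Da)))
        s1 = sla.cho_solve(cf, rhs1, check_finite=False)
        r = self.yty - self.b1 @ s1
        if Da is not None:
            ua = (self.ba - self.M1a.T @ s1) / Da
            # r = y'y - b's over the full system; the absorbed part enters
            # through ua and the modified rhs already contains the coupling
            r = self.yty - self.b1 @ s1 - self.ba @ ua
        if r <= 0 or not np.isfinite(logdet):
            return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
        obj = nmp * np.log(r) + logdet + sum(
            q * t for q, t in zip(self.q, theta)
        )
        if not want_grad:
            return obj
        Sinv = _chol_inverse(cf)
        diag1 = np.diag(Sinv)
        grad = np.empty_like(theta)
        for i, f in enumerate(self.names):
            g = gamma[f]
            if f == self.absorb:
                u2 = float(ua @ ua)
                if self.M1a_dense is None:
                    self.M1a_dense = self.M1a.toarray()
                G = Sinv @ self.M1a_dense
                quad = np.einsum("ij,ij->j", self.M1a_dense, G)
                tr = float(np.sum(1.0 / Da + quad / Da**2))
            else:
                sl = self.slices[f]
                u2 = float(s1[sl] @ s1[sl])
                tr = float(diag1[sl].sum())
            grad[i] = -(nmp * u2 / r + tr) / g + self.q[i]
        return obj, grad

    def solution(self, gamma_values):
        """beta-hat, per-factor u-hat and y'Py at the given ratios."""
        gamma = {f: g for f, g in zip(self.names, gamma_values)}
        S, Da, rhs1, _ = self._assemble(gamma)
        cf = sla.cho_factor(S, lower=True, check_finite=False)
        s1 = sla.cho_solve(cf, rhs1, check_finite=False)
        r = self.yty - self.b1 @ s1
        us = []
        for f in self.names:
            if f == self.absorb:
                ua = (self.ba - self.M1a.T @ s1) / Da
                r -= self.ba @ ua
                us.append(ua)
            else:
                sl = self.slices[f]
                us.append(s1[sl])
        return s1[: self.p], us, float(r)


def _optimize(problem: _REMLProblem, theta0, max_iter=200,
              ftol=1e-15, gtol=1e-9):
    trace = []
    res = opt.minimize(
        problem.objective,
        theta0,
        args=(True,),
        jac=True,
        method="L-BFGS-B",
        bounds=[_LOG_BOUNDS] * len(theta0),
        options={"ftol": ftol, "gtol": gtol, "maxiter": max_iter},
    )
    trace.append(("lbfgsb", res.nit, float(res.fun)))
    if not np.isfinite(res.fun):
        raise ConvergenceError(
            "REML objective non-finite at optimum", trace=trace
        )
    theta, fval = np.asarray(res.x, dtype=float), float(res.fun)
    if gtol <= 1e-9 and len(theta):
        # Newton polish: the REML surface is very flat along components
        # with few levels (environment, replicate), where L-BFGS stops
        # ~1e-6 short in the parameters; a few Newton steps with a
        # finite-difference Hessian of the analytic gradient fix that
        theta, fval, n_newton = _newton_polish(problem, theta, fval)
        trace.append(("newton-polish", n_newton, fval))
    return theta, fval, res.nit, trace


def _newton_polish(problem, theta, fval, max_steps=8, h=1e-5):
    k = len(theta)
    for step in range(max_steps):
        _, grad = problem.objective(theta, True)
        if np.linalg.norm(grad) < 1e-10:
            break
        H = np.empty((k, k))
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            _, gp = problem.objective(theta + e, True)
            _, gm = problem.objective(theta - e, True)
            H[:, j] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            delta = np.linalg.solve(H + 1e-10 * np.eye(k), -grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        for scale in (1.0, 0.5, 0.25, 0.1):
            cand = np.clip(theta + scale * delta, *_LOG_BOUNDS)
            f_new = problem.objective(cand)
            if np.isfinite(f_new) and f_new <= fval + 1e-12:
                theta, fval, improved = cand, float(f_new), True
                break
        if not improved:
            break
    return theta, fval, step + 1


def _reml(y, X, Z: dict, init_gamma: dict | None = None, max_iter=200):
    """REML fit with boundary handling; returns components and solution."""
    names = list(Z)
    theta0 = np.array(
        [np.log(init_gamma.get(f, 0.3)) if init_gamma else np.log(0.3) for f in names]
    )
    active = list(range(len(names)))
    trace_all = []
    total_it = 0
    if not names:
        problem = _REMLProblem(y, X, {})
        theta = np.array([])
        fval = (
            float(problem.objective(theta))
            if problem.n > problem.p
            else float("nan")  # saturated fixed model: exact fit, no REML
        )
    while names:
        sub_Z = {names[i]: Z[names[i]] for i in active}
        problem = _REMLProblem(y, X, sub_Z)
        try:
            theta, fval, nit, trace = _optimize(
                problem, theta0[active], max_iter=max_iter
            )
        except ConvergenceError:
            # an exactly-fit response (zero residual) has an unbounded REML
            # objective; return the exact solution with zero variances
            _, _, r_chk = problem.solution(np.exp(theta0[active]))
            if r_chk <= 1e-12 * max(problem.yty, 1.0):
                theta = np.full(len(active), _LOG_BOUNDS[0])
                fval = float("nan")
                trace_all.append(("exact-fit", 0, 0.0))
                break
            raise
        trace_all.extend(trace)
        total_it += nit
        gamma = np.exp(theta)
        at_floor = [i for i, g in zip(active, gamma) if g < _GAMMA_FLOOR]
        if not at_floor:
            break
        # boundary constraint: fix those components at zero, re-optimise
        keep = [i for i in active if i not in at_floor]
        for i, g in zip(active, gamma):
            theta0[i] = np.log(max(g, _GAMMA_FLOOR))
        active = keep
        if not active:
            problem = _REMLProblem(y, X, {})
            theta = np.array([])
            fval = problem.objective(theta) if problem.dim else np.nan
            break

    beta, us, r = problem.solution(np.exp(theta))
    nmp = problem.n - problem.p
    sigma2_eps = r / nmp if nmp > 0 else 0.0
    gammas = {f: 0.0 for f in names}
    active_names = [names[i] for i in active]
    for j, f in enumerate(active_names):
        gammas[f] = float(np.exp(theta[j]))
    sigma2 = {f: gammas[f] * sigma2_eps for f in names}
    u_full = {f: np.zeros(Z[f].shape[1]) for f in names}
    for j, f in enumerate(active_names):
        u_full[f] = us[j]
    # full restricted log-likelihood at the optimum (constants included)
    if nmp > 0 and np.isfinite(fval):
        loglik = -0.5 * (
            fval + nmp * (1.0 + np.log(2.0 * np.pi) - np.log(nmp))
        )
    else:
        loglik = float("nan")
    return {
        "beta": beta,
        "u": u_full,
        "sigma2": sigma2,
        "sigma2_eps": float(sigma2_eps),
        "gamma": gammas,
        "loglik": float(loglik),
        "n_iter": total_it,
        "trace": trace_all,
    }


# ---------------------------------------------------------------------------
# public operations


def fit_plot_model(
    plots: pd.DataFrame,
    trait: str,
    genotype_fixed: bool = False,
    init_gamma: dict | None = None,
    max_iter: int = 200,
) -> ModelFit:
    """REML fit of the multi-environment plot model for one trait.

    With ``genotype_fixed=False`` all factors are random and the fit yields
    the variance components entering broad-sense heritability.  With
    ``genotype_fixed=True`` the genotype enters as a fixed cell-means factor
    and the fixed-effect estimates are the BLUEs used downstream as the
    per-genotype phenotype.
    """
    y, X, Z, meta = _build_design(plots, trait, genotype_fixed)
    res = _reml(y, X, Z, init_gamma=init_gamma, max_iter=max_iter)

    obs = meta["obs"]
    ne = meta["n_env"]
    reps_per_env = obs.groupby("environment")["replicate"].nunique()
    nr = float(reps_per_env.mean())

    def comp(f):
        if f in Z:
            return float(res["sigma2"][f])
        return None

    vc = VarianceComponents(
        sigma2_g=comp("genotype") if not genotype_fixed else None,
        sigma2_gxe=comp("gxe"),
        sigma2_env=comp("env"),
        sigma2_rep=comp("rep"),
        sigma2_block=comp("block"),
        sigma2_eps=res["sigma2_eps"],
        ne=ne,
        nr=nr,
    )
    fit = ModelFit(
        mode="genotype-fixed" if genotype_fixed else "all-random",
        mu=float(res["beta"].mean()) if genotype_fixed else float(res["beta"][0]),
        vc=vc,
        loglik=res["loglik"],
        converged=True,
        n_iter=res["n_iter"],
        gamma=res["gamma"],
        trace=res["trace"],
    )
    if genotype_fixed:
        fit.blues = pd.Series(
            res["beta"], index=pd.Index(meta["genotype_levels"], name="genotype")
        )
    else:
        fit.genotype_effects = pd.Series(
            res["u"]["genotype"],
            index=pd.Index(meta["genotype_levels"], name="genotype"),
        )
    return fit


def fit_plot_model_multi(
    plots: pd.DataFrame,
    traits: list[str],
    genotype_fixed: bool = False,
    max_iter: int = 200,
) -> dict[str, ModelFit]:
    """Fit the plot model to many complete responses on one shared design.

    All responses must be observed on exactly the same plots (true for
    processed spectra, where every wavelength is measured on every plot);
    the mixed-model coefficient structure is then built once and only the
    response-dependent parts are recomputed, with the variance-ratio
    estimates warm-starting the next response.  Components at the lower
    boundary are reported as zero without the re-fit pass of
    :func:`fit_plot_model` (immaterial at a ratio of 1e-7).
    """
    first = traits[0]
    mask = plots[first].notna()
    for t in traits[1:]:
        if not mask.equals(plots[t].notna()):
            raise DesignError(
                "multi-response fit requires an identical observation "
                "pattern for all responses"
            )
    y0, X, Z, meta = _build_design(plots, first, genotype_fixed)
    obs = meta["obs"]
    ne = meta["n_env"]
    nr = float(obs.groupby("environment")["replicate"].nunique().mean())
    problem = _REMLProblem(y0, X, Z)
    names = list(Z)
    theta = np.full(len(names), np.log(0.3))
    fits: dict[str, ModelFit] = {}
    obs_all = plots.loc[mask].reset_index(drop=True)
    for t in traits:
        problem.set_response(obs_all[t].to_numpy(dtype=float))
        if not names or problem.n == problem.p:
            # nothing to optimise: saturated fixed model or no random terms
            theta, fval, nit, trace = theta, float("nan"), 0, []
        else:
            try:
                # variance ratios need far less precision than the
                # single-trait path: BLUEs are insensitive to them and H2
                # tolerances are generous
                theta, fval, nit, trace = _optimize(
                    problem, theta, max_iter=max_iter, ftol=1e-11, gtol=1e-6
                )
            except ConvergenceError:
                _, _, r_chk = problem.solution(np.exp(theta))
                if r_chk <= 1e-12 * max(problem.yty, 1.0):
                    theta = np.full(len(names), _LOG_BOUNDS[0])
                    fval, nit, trace = float("nan"), 0, [("exact-fit", 0, 0.0)]
                else:
                    raise
        gamma = np.exp(theta)
        beta, us, r = problem.solution(gamma)
        nmp = problem.n - problem.p
        sigma2_eps = r / nmp if nmp > 0 else 0.0
        sig = {
            f: (0.0 if g < _GAMMA_FLOOR else float(g * sigma2_eps))
            for f, g in zip(names, gamma)
        }
        vc = VarianceComponents(
            sigma2_g=sig.get("genotype") if not genotype_fixed else None,
            sigma2_gxe=sig.get("gxe"),
            sigma2_env=sig.get("env"),
            sigma2_rep=sig.get("rep"),
            sigma2_block=sig.get("block"),
            sigma2_eps=float(sigma2_eps),
            ne=ne,
            nr=nr,
        )
        loglik = (
            -0.5 * (fval + nmp * (1.0 + np.log(2.0 * np.pi) - np.log(nmp)))
            if nmp > 0 and np.isfinite(fval)
            else float("nan")
        )
        fit = ModelFit(
            mode="genotype-fixed" if genotype_fixed else "all-random",
            mu=float(beta.mean()) if genotype_fixed else float(beta[0]),
            vc=vc,
            loglik=float(loglik),
            converged=True,
            n_iter=nit,
            gamma={f: float(g) for f, g in zip(names, gamma)},
            trace=trace,
        )
        if genotype_fixed:
            fit.blues = pd.Series(
                beta, index=pd.Index(meta["genotype_levels"], name="genotype")
            )
        else:
            gi = names.index("genotype")
            fit.genotype_effects = pd.Series(
                us[gi], index=pd.Index(meta["genotype_levels"], name="genotype")
            )
        fits[t] = fit
        theta = np.clip(theta, np.log(1e-6), None)  # warm start, off the floor
    return fits


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H2 = sigma2_g / (sigma2_g + sigma2_gxe/ne + sigma2_eps/(ne*nr)).
    """
    if vc.sigma2_g is None:
        raise UndefinedStatisticError("genotypic variance not estimated")
    if vc.sigma2_gxe is None:
        raise UndefinedStatisticError(
            "genotype-by-environment variance inestimable for this design"
        )
    if vc.ne < 1 or vc.nr < 1:
        raise UndefinedStatisticError("ne and nr must be >= 1")
    denom = vc.sigma2_g + vc.sigma2_gxe / vc.ne + vc.sigma2_eps / (vc.ne * vc.nr)
    if denom == 0:
        raise UndefinedStatisticError("all variance components are zero")
    return vc.sigma2_g / denom


def group_heritabilities(
    plots: pd.DataFrame,
    trait: str,
    group_map: pd.DataFrame,
    level: str = "subgroup",
) -> dict:
    """Group-specific broad-sense heritabilities.

    Group-specific genotypic and g-x-e variances are obtained by fitting the
    plot model separately on each group's plots (equivalent to a
    dummy-variable heterogeneous-variance fit for disjoint groups); groups
    with fewer than two genotypes are skipped with a warning.
    """
    _require_columns(plots)
    if level not in group_map.columns:
        raise DesignError(f"group map lacks column {level!r}")
    mapping = group_map.set_index("genotype_id")[level]
    out = {}
    for grp, members in mapping.groupby(mapping):
        ids = set(members.index)
        sub = plots[plots["genotype"].isin(ids)]
        if sub["genotype"].nunique() < 2:
            warnings.warn(f"group {grp!r} has <2 genotypes; skipped")
            continue
        fit = fit_plot_model(sub, trait, genotype_fixed=False)
        try:
            out[grp] = heritability(fit.vc)
        except UndefinedStatisticError:
            out[grp] = np.nan
    return out


def compute_blues(
    plots: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """BLUEs per genotype for each trait (genotype fixed in the plot model).

    In balanced orthogonal designs these equal the arithmetic genotype
    means; in unbalanced designs they are the generalized-least-squares
    genotype estimates given the REML variance components.
    """
    _require_columns(plots)
    if traits is None:
        traits = [c for c in plots.columns if c not in KEY_COLUMNS]
    cols = {}
    for trait in traits:
        fit = fit_plot_model(plots, trait, genotype_fixed=True)
        cols[trait] = fit.blues
    return pd.DataFrame(cols)


def detect_outliers(
    plots: pd.DataFrame, trait: str, alpha: float = 0.05
) -> pd.Series:
    """Bonferroni-Holm outlier screen on plot-model residuals.

    Residuals of the all-random plot-model fit are standardized and turned
    into two-sided normal p-values; the Holm step-down procedure at
    family-wise level ``alpha`` flags outliers.  Flagged plots are set to
    missing and the screen is re-run once; the union of both passes is
    returned as a boolean Series aligned with ``plots``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if plots[trait].notna().sum() < 10:
        raise DesignError("need at least 10 non-missing plots for the screen")
    flags = pd.Series(False, index=plots.index)
    work = plots.copy()
    for _ in range(2):
        mask = work[trait].notna()
        y, X, Z, meta = _build_design(work, trait, genotype_fixed=False)
        res = _reml(y, X, Z)
        fitted = np.asarray(
            (X @ res["beta"]).ravel()
            + sum(Z[f] @ res["u"][f] for f in Z)
        )
        resid = y - fitted
        sd = resid.std(ddof=1)
        if sd == 0:
            break
        z = resid / sd
        from scipy.stats import norm

        pvals = 2.0 * norm.sf(np.abs(z))
        reject, *_ = multipletests(pvals, alpha=alpha, method="holm")
        if not reject.any():
            break
        idx = work.index[mask][reject]
        flags.loc[idx] = True
        work.loc[idx, trait] = np.nan
    return flags
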
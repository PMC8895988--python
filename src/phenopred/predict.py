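"""Ridge-regression BLUP, predictor-agnostic (markers or wavelengths).

The model is y = X beta + Z u + eps with u ~ N(0, V_u I) iid over the p
predictor columns and eps ~ N(0, V_e I).  The single variance ratio
lambda = V_e / V_u is estimated by REML on the profile likelihood after one
eigendecomposition of the n x n kernel Z Z' projected onto the fixed-effect
complement; no per-iteration matrix factorisation is needed.  Effects are
recovered as u = V_u Z' V^{-1} (y - X beta).

The equivalent kernel (GBLUP) formulation — genotype effects g ~ N(0,
V_g K) with K = Z Z' — is provided as an independent route to the same
predictions and serves as the module's central algebraic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .errors import UndefinedStatisticError

__all__ = ["RRModel", "solve_rrblup", "predict_new", "gblup_equiv",
           "reml_profile", "LAMBDA_BOUNDS"]

#: search interval for the variance ratio lambda = V_e / V_u
LAMBDA_BOUNDS = (1e-5, 1e5)


@dataclass
class RRModel:
    """Fitted ridge-BLUP state; predictions need nothing beyond it."""

    beta: np.ndarray  # fixed effects (intercept only by default)
    u: np.ndarray  # predictor effects, length p
    v_u: float
    v_e: float
    lam: float  # V_e / V_u
    feature_ids: list
    training_ids: list
    loglik: float
    provenance: str = "unknown"
    extra: dict = field(default_factory=dict)


def _as_matrix(Z):
    if isinstance(Z, pd.DataFrame):
        return (
            Z.to_numpy(dtype=float),
            list(Z.columns),
            list(Z.index),
            Z.attrs.get("provenance", "unknown"),
        )
    Z = np.asarray(Z, dtype=float)
    return Z, list(range(Z.shape[1])), list(range(Z.shape[0])), "unknown"


def reml_profile(y, Z, X=None):
    """Eigendecomposition and the REML profile objective in log-lambda.

    Returns (objective, xi, eta, Q2) where f(log lam) is minus twice the
    restricted profile log-likelihood up to a constant:
    f = (n-p) log(sum eta_i^2/(xi_i+lam)) + sum log(xi_i+lam).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    K = Z @ Z.T
    Q = sla.qr(X, mode="full")[0]
    Q2 = Q[:, p:]  # orthonormal basis of the fixed-effect complement
    M = Q2.T @ K @ Q2
    xi, U = sla.eigh(M)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (Q2.T @ y)

    def objective(log_lam):
        lam = np.exp(log_lam)
        w = xi + lam
        q = np.sum(eta**2 / w)
        return (n - p) * np.log(q) + np.sum(np.log(w))

    return objective, xi, eta, Q2


def solve_rrblup(y, Z, X=None) -> RRModel:
    """REML fit of the ridge model; spectral profile likelihood in lambda.

    ``y`` are the per-genotype BLUEs (aligned to the rows of ``Z`` by
    position or by a shared pandas index); ``Z`` is the predictor matrix
    (dosages or standardized spectral derivatives).  The intercept is the
    only fixed effect unless ``X`` is given.
    """
    Zm, feature_ids, row_ids, provenance = _as_matrix(Z)
    if isinstance(y, pd.Series) and isinstance(Z, pd.DataFrame):
        y = y.reindex(Z.index)
        if y.isna().any():
            raise ValueError("y is missing values for some rows of Z")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if Zm.shape[0] != n:
        raise ValueError(f"y length {n} != rows of Z {Zm.shape[0]}")
    if np.var(y) == 0:
        raise UndefinedStatisticError("no signal: y has zero variance")
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]

    objective, xi, eta, _ = reml_profile(y, Zm, X)
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError(
            f"non-finite REML profile likelihood at log-lambda {res.x}"
        )
    lam = float(np.exp(res.x))
    w = xi + lam
    v_u = float(np.sum(eta**2 / w) / (n - p))
    v_e = lam * v_u

    K = Zm @ Zm.T
    H = K + lam * np.eye(n)
    cf = sla.cho_factor(H, lower=True, check_finite=False)
    Hiy = sla.cho_solve(cf, y, check_finite=False)
    HiX = sla.cho_solve(cf, X, check_finite=False)
    beta = sla.solve(X.T @ HiX, X.T @ Hiy, assume_a="sym")
    resid = y - X @ beta
    u = Zm.T @ sla.cho_solve(cf, resid, check_finite=False)

    loglik = -0.5 * (
        res.fun + (n - p) * (1.0 + np.log(2.0 * np.pi) - np.log(n - p))
    )
    return RRModel(
        beta=np.asarray(beta, dtype=float),
        u=np.asarray(u, dtype=float),
        v_u=v_u,
        v_e=v_e,
        lam=lam,
        feature_ids=feature_ids,
        training_ids=row_ids,
        loglik=float(loglik),
        provenance=provenance,
    )


def predict_new(model: RRModel, Z_new, X_new=None) -> pd.Series:
    """Predicted values for new rows: yhat = X_new beta + Z_new u.

    Columns of ``Z_new`` must match the model's feature ids exactly, in
    order and identity.
    """
    if isinstance(Z_new, pd.DataFrame):
        new_feats = list(Z_new.columns)
        if new_feats != list(model.feature_ids):
            missing = [f for f in model.feature_ids if f not in set(new_feats)]
            extra = [f for f in new_feats if f not in set(model.feature_ids)]
            raise ValueError(
                f"feature mismatch: missing {missing[:5]}..., extra {extra[:5]}..."
                if missing or extra
                else "feature order differs from the fitted model"
            )
        idx = Z_new.index
        Zm = Z_new.to_numpy(dtype=float)
    else:
        Zm = np.asarray(Z_new, dtype=float)
        if Zm.shape[1] != len(model.feature_ids):
            raise ValueError(
                f"feature mismatch: model has {len(model.feature_ids)} "
                f"features, Z_new has {Zm.shape[1]}"
            )
        idx = pd.RangeIndex(Zm.shape[0])
    if X_new is None:
        X_new = np.ones((Zm.shape[0], 1))
    yhat = X_new @ model.beta + Zm @ model.u
    return pd.Series(np.asarray(yhat, dtype=float), index=idx)


def gblup_equiv(y, Z, Z_new=None) -> pd.Series:
    """Predictions via the kernel (GBLUP) route; algebraically identical.

    Fits genotype effects g ~ N(0, V_g K), K = Z Z', by the same spectral
    REML, and predicts new rows through the cross-kernel Z_new Z'.  Used as
    the internal correctness oracle for the marker-effect route.
    """
    Zm, _, _, _ = _as_matrix(Z)
    if isinstance(y, pd.Series) and isinstance(Z, pd.DataFrame):
        y = y.reindex(Z.index)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = np.ones((n, 1))

    objective, xi, eta, _ = reml_profile(y, Zm, X)
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))

    K = Zm @ Zm.T
    H = K + lam * np.eye(n)
    try:
        cf = sla.cho_factor(H, lower=True, check_finite=False)
    except sla.LinAlgError:
        # numerically indefinite kernel: add jitter, keep going
        H = H + 1e-8 * np.trace(K) / n * np.eye(n)
        cf = sla.cho_factor(H, lower=True, check_finite=False)
    Hiy = sla.cho_solve(cf, y, check_finite=False)
    HiX = sla.cho_solve(cf, X, check_finite=False)
    beta = sla.solve(X.T @ HiX, X.T @ Hiy, assume_a="sym")
    alpha = sla.cho_solve(cf, y - X @ beta, check_finite=False)

    if Z_new is None:
        Zn, idx = Zm, (Z.index if isinstance(Z, pd.DataFrame) else
                       pd.RangeIndex(n))
    elif isinstance(Z_new, pd.DataFrame):
        Zn, idx = Z_new.to_numpy(dtype=float), Z_new.index
    else:
        Zn = np.asarray(Z_new, dtype=float)
        idx = pd.RangeIndex(Zn.shape[0])
    K_cross = Zn @ Zm.T
    yhat = (np.ones((Zn.shape[0], 1)) @ beta) + K_cross @ alpha
    return pd.Series(np.asarray(yhat, dtype=float).ravel(), index=idx)
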
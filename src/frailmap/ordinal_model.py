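"""Weighted proportional-odds ordinal regression for frailty categories.

Model
-----
For ordered categories robust < pre_frail < frail coded 0 < 1 < 2, the
cumulative probabilities are

    P(Y <= k | x) = expit(theta_k - x' beta),   k in {1, 2},

with theta_1 < theta_2.  Positive coefficients therefore mean *more* frail.
Predictors are indicator-coded: age bands 55-59 ... 90+ against reference
50-54, female against male, IMD quintiles 2..5 against quintile 1 (most
deprived).

Estimation maximises the weighted log-likelihood
``sum_i w_i log P(Y_i = y_i | x_i)`` by damped Newton with analytic
gradient and Hessian, falling back to L-BFGS-B when a Newton step fails.
The default covariance is the inverse observed information of the weighted
likelihood; a robust (sandwich) covariance is available via
``cov_type="sandwich"``.  With inverse-probability weights the likelihood
is a pseudo-likelihood, so likelihood-ratio p-values are approximate.

Multiple-imputation fits are combined with Rubin's rules: pooled point =
mean of the m estimates, total covariance T = Wbar + (1 + 1/m) B where
Wbar is the mean within-imputation covariance and B the between-imputation
sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .strata import AGE_BANDS, CATEGORIES, QUINTILES, stratum_grid

__all__ = [
    "OrdinalFit",
    "PooledFit",
    "build_design",
    "fit_proportional_odds",
    "pool_rubin",
    "predict_strata",
    "lrt_interaction",
]

_THETA_NAMES = ("theta_1", "theta_2")


@dataclass
class OrdinalFit:
    """A converged weighted proportional-odds fit."""

    params: pd.Series      # betas followed by theta_1, theta_2
    cov: pd.DataFrame
    loglik: float          # weighted log-likelihood at the optimum
    n: int
    sum_weights: float
    n_iter: int
    converged: bool

    @property
    def beta(self) -> pd.Series:
        return self.params.drop(list(_THETA_NAMES))

    @property
    def thetas(self) -> tuple[float, float]:
        return float(self.params["theta_1"]), float(self.params["theta_2"])


@dataclass
class PooledFit:
    """Rubin-pooled estimates across m imputation fits."""

    params: pd.Series
    cov: pd.DataFrame          # total covariance T
    within: pd.DataFrame       # Wbar
    between: pd.DataFrame      # B
    m: int


def build_design(
    table: pd.DataFrame, include_age_sex_interaction: bool = False
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Indicator design matrix, outcome codes and weights from a scored table.

    Returns ``(X, names, y, w)``.  ``y`` codes robust/pre_frail/frail as
    0/1/2.  If the table has no ``weight`` column all weights are 1.
    """
    for col in ("age_band", "sex", "imd_quintile", "frailty_category"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")

    cat_codes = {c: i for i, c in enumerate(CATEGORIES)}
    y_raw = table["frailty_category"].astype(str)
    unknown = set(y_raw) - set(cat_codes)
    if unknown:
        raise ValueError(f"unknown frailty categories: {sorted(unknown)}")
    y = y_raw.map(cat_codes).to_numpy()

    cols: list[np.ndarray] = []
    names: list[str] = []
    band = table["age_band"].to_numpy()
    for b in AGE_BANDS[1:]:
        cols.append((band == b).astype(float))
        names.append(f"age_{b}")
    female = (table["sex"].to_numpy() == "female").astype(float)
    cols.append(female)
    names.append("sex_female")
    q = table["imd_quintile"].to_numpy()
    for qq in QUINTILES[1:]:
        cols.append((q == qq).astype(float))
        names.append(f"imd_{qq}")
    if include_age_sex_interaction:
        for b in AGE_BANDS[1:]:
            cols.append((band == b).astype(float) * female)
            names.append(f"age_{b}:sex_female")
    X = np.column_stack(cols)

    if "weight" in table.columns:
        w = table["weight"].to_numpy(dtype=float)
        if (w <= 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be positive and finite")
    else:
        w = np.ones(len(table))
    return X, names, y, w


def _loglik_parts(params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Per-observation probabilities and z-derivative ingredients."""
    p_pred = X.shape[1]
    beta = params[:p_pred]
    t1, t2 = params[p_pred], params[p_pred + 1]
    if not t1 < t2:
        return None
    eta = X @ beta
    z1, z2 = t1 - eta, t2 - eta
    F1, F2 = expit(z1), expit(z2)
    prob = np.where(y == 0, F1, np.where(y == 1, F2 - F1, 1.0 - F2))
    if (prob <= 0).any():
        return None
    return eta, F1, F2, prob


def _loglik_grad_hess(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray,
    want_hessian: bool = True, want_scores: bool = False,
):
    """Weighted log-likelihood, gradient and (optionally) Hessian.

    Returns ``(ll, grad, hess, scores)`` in the (beta, theta_1, theta_2)
    parameterisation; ``None`` if the parameters are infeasible
    (theta_1 >= theta_2 or a zero-probability observation).
    """
    parts = _loglik_parts(params, X, y)
    if parts is None:
        return None
    _, F1, F2, prob = parts
    ll = float(w @ np.log(prob))

    f1 = F1 * (1.0 - F1)
    f2 = F2 * (1.0 - F2)
    is0, is1, is2 = y == 0, y == 1, y == 2

    d1 = np.zeros_like(prob)
    d2 = np.zeros_like(prob)
    d1[is0] = 1.0 - F1[is0]
    d1[is1] = -f1[is1] / prob[is1]
    d2[is1] = f2[is1] / prob[is1]
    d2[is2] = -F2[is2]

    g_beta = -X.T @ (w * (d1 + d2))
    grad = np.concatenate([g_beta, [float(w @ d1), float(w @ d2)]])

    hess = None
    if want_hessian:
        f1p = f1 * (1.0 - 2.0 * F1)   # d f1 / d z1
        f2p = f2 * (1.0 - 2.0 * F2)
        h11 = np.zeros_like(prob)
        h12 = np.zeros_like(prob)
        h22 = np.zeros_like(prob)
        h11[is0] = -f1[is0]
        p1 = prob[is1]
        h11[is1] = (-f1p[is1] * p1 - f1[is1] ** 2) / p1**2
        h22[is1] = (f2p[is1] * p1 - f2[is1] ** 2) / p1**2
        h12[is1] = f1[is1] * f2[is1] / p1**2
        h22[is2] = -f2[is2]

        wh11, wh12, wh22 = w * h11, w * h12, w * h22
        p_pred = X.shape[1]
        k = p_pred + 2
        H = np.zeros((k, k))
        H[:p_pred, :p_pred] = X.T @ (X * (wh11 + 2 * wh12 + wh22)[:, None])
        Hb1 = -X.T @ (wh11 + wh12)
        Hb2 = -X.T @ (wh12 + wh22)
        H[:p_pred, p_pred] = Hb1
        H[p_pred, :p_pred] = Hb1
        H[:p_pred, p_pred + 1] = Hb2
        H[p_pred + 1, :p_pred] = Hb2
        H[p_pred, p_pred] = wh11.sum()
        H[p_pred, p_pred + 1] = wh12.sum()
        H[p_pred + 1, p_pred] = wh12.sum()
        H[p_pred + 1, p_pred + 1] = wh22.sum()
        hess = H

    scores = None
    if want_scores:
        # per-observation weighted score vectors, for sandwich covariance
        sb = -X * (w * (d1 + d2))[:, None]
        scores = np.column_stack([sb, w * d1, w * d2])
    return ll, grad, hess, scores


def fit_proportional_odds(
    table: pd.DataFrame,
    include_age_sex_interaction: bool = False,
    cov_type: str = "information",
    max_iter: int = 100,
    gtol: float = 1e-8,
) -> OrdinalFit:
    """Fit the weighted proportional-odds model to a scored survey table.

    ``table`` needs columns age_band, sex, imd_quintile, frailty_category
    and (optionally) weight.  Convergence requires the infinity norm of the
    mean-log-likelihood gradient to fall below ``gtol``.

    Raises if an outcome category is absent from the data or the optimiser
    fails to converge (which includes perfect separation, where estimates
    diverge).
    """
    X, names, y, w = build_design(table, include_age_sex_interaction)
    # drop constant indicator columns (levels absent from the data, or data
    # where everyone shares a level): they carry no information and would
    # make the observed information singular.  Predictions for dropped
    # levels fall back to the reference level.
    keep = [j for j in range(X.shape[1]) if X[:, j].min() != X[:, j].max()]
    X = X[:, keep]
    names = [names[j] for j in keep]
    counts = np.bincount(y, minlength=3)
    if (counts == 0).any():
        absent = [CATEGORIES[i] for i in range(3) if counts[i] == 0]
        raise ValueError(f"outcome category absent from data: {absent}")
    if cov_type not in ("information", "sandwich"):
        raise ValueError("cov_type must be 'information' or 'sandwich'")

    sum_w = float(w.sum())
    # start from the null model: thetas at weighted cumulative shares, beta 0
    share_rob = float(w[y == 0].sum() / sum_w)
    share_rob_pre = float(w[y <= 1].sum() / sum_w)
    params = np.concatenate([
        np.zeros(X.shape[1]), [logit(share_rob), logit(share_rob_pre)]
    ])

    ll, grad, hess, _ = _loglik_grad_hess(params, X, y, w)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) / sum_w <= gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = None
        moved = False
        if step is not None:
            lam = 1.0
            for _ in range(30):   # damping: halve until the likelihood improves
                cand = params - lam * step
                res = _loglik_grad_hess(cand, X, y, w)
                if res is not None and res[0] >= ll - 1e-12:
                    params, (ll, grad, hess) = cand, res[:3]
                    moved = True
                    break
                lam *= 0.5
        if not moved:
            params, ll = _quasi_newton_fallback(params, X, y, w)
            res = _loglik_grad_hess(params, X, y, w)
            if res is None:
                break
            ll, grad, hess, _ = res
    else:
        n_iter = max_iter
    if not converged and np.max(np.abs(grad)) / sum_w <= gtol:
        converged = True
    if not converged:
        raise RuntimeError(
            "proportional-odds fit did not converge "
            f"(|grad|_inf/sum_w = {np.max(np.abs(grad)) / sum_w:.3g} after "
            f"{n_iter} iterations); check for perfect separation or sparse "
            "outcome categories"
        )

    ll, grad, hess, scores = _loglik_grad_hess(
        params, X, y, w, want_scores=(cov_type == "sandwich")
    )
    info = -hess
    cov = np.linalg.inv(info)
    if cov_type == "sandwich":
        B = scores.T @ scores
        cov = cov @ B @ cov
    cov = 0.5 * (cov + cov.T)

    all_names = names + list(_THETA_NAMES)
    return OrdinalFit(
        params=pd.Series(params, index=all_names),
        cov=pd.DataFrame(cov, index=all_names, columns=all_names),
        loglik=ll,
        n=len(y),
        sum_weights=sum_w,
        n_iter=n_iter,
        converged=True,
    )


def _quasi_newton_fallback(params, X, y, w):
    """L-BFGS-B refinement on the mean negative log-likelihood, used when a
    damped Newton step cannot improve the objective."""
    sum_w = float(w.sum())

    def nll_and_grad(p):
        res = _loglik_grad_hess(p, X, y, w, want_hessian=False)
        if res is None:
            return 1e12, np.zeros_like(p)
        ll, grad = res[0], res[1]
        return -ll / sum_w, -grad / sum_w

    opt = minimize(
        nll_and_grad, params, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    return opt.x, -opt.fun * sum_w


def pool_rubin(fits: list[OrdinalFit]) -> PooledFit:
    """Combine m imputation fits with Rubin's rules.

    Point = mean of the estimates; total covariance
    T = Wbar + (1 + 1/m) B with B the between-imputation sample covariance
    (zero when m = 1).
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit to pool")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ValueError("fits have mismatched parameter names")
    m = len(fits)
    points = np.stack([f.params.to_numpy() for f in fits])
    covs = np.stack([f.cov.to_numpy() for f in fits])
    point = points.mean(axis=0)
    wbar = covs.mean(axis=0)
    if m > 1:
        dev = points - point
        between = dev.T @ dev / (m - 1)
    else:
        between = np.zeros_like(wbar)
    total = wbar + (1.0 + 1.0 / m) * between
    return PooledFit(
        params=pd.Series(point, index=index),
        cov=pd.DataFrame(total, index=index, columns=index),
        within=pd.DataFrame(wbar, index=index, columns=index),
        between=pd.DataFrame(between, index=index, columns=index),
        m=m,
    )


def _stratum_design(param_names: pd.Index) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix rows for all 90 strata, matching the beta names."""
    grid = stratum_grid()
    beta_names = [n for n in param_names if n not in _THETA_NAMES]
    X = np.zeros((len(grid), len(beta_names)))
    female = (grid["sex"] == "female").to_numpy().astype(float)
    for j, name in enumerate(beta_names):
        if name.startswith("age_") and ":" not in name:
            X[:, j] = (grid["age_band"] == name[4:]).astype(float)
        elif name == "sex_female":
            X[:, j] = female
        elif name.startswith("imd_"):
            X[:, j] = (grid["imd_quintile"] == int(name[4:])).astype(float)
        elif ":" in name:   # age_band x sex interaction indicator
            band = name.split(":")[0][4:]
            X[:, j] = (grid["age_band"] == band).astype(float) * female
        else:
            raise ValueError(f"unrecognised parameter name {name!r}")
    return grid, X


def predict_strata(fit: OrdinalFit | PooledFit) -> pd.DataFrame:
    """Predicted category probabilities for all 90 strata.

    p_robust = expit(theta_1 - x'beta), p_prefrail = expit(theta_2 - x'beta)
    - p_robust, p_frail = the remainder; rows sum to 1 by construction.
    """
    grid, X = _stratum_design(fit.params.index)
    beta = fit.params.drop(list(_THETA_NAMES)).to_numpy()
    t1, t2 = fit.params["theta_1"], fit.params["theta_2"]
    eta = X @ beta
    c1, c2 = expit(t1 - eta), expit(t2 - eta)
    out = grid.copy()
    out["p_robust"] = c1
    out["p_prefrail"] = c2 - c1
    out["p_frail"] = 1.0 - c2
    return out


def lrt_interaction(
    null_fit: OrdinalFit, alt_fit: OrdinalFit, tol: float = 1e-6
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair of fits on the same data.

    Returns ``(statistic, df, p_value)`` with the chi-square upper tail.
    Under inverse-probability weighting this is an approximate
    (pseudo-likelihood) test.
    """
    df = len(alt_fit.params) - len(null_fit.params)
    if df < 0:
        raise ValueError("alternative model must nest the null model")
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if stat < -tol * max(1.0, abs(null_fit.loglik)):
        raise ValueError(
            f"alternative log-likelihood below null ({stat/2:.6g}); "
            "models are not nested or a fit did not converge"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p
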
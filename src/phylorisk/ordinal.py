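"""Proportional-odds (ordered logistic) regression for red-list status.

Red-list categories are encoded on the ordinal threat scale
LC = 0, NT = 1, VU = 2, EN = 3, CR = 4.  The model is the cumulative
logit model with the latent-variable sign convention

    P(Y ≤ k | x) = logistic(ζ_k − xβ),   ζ₁ < … < ζ_{K−1},

so a positive β moves probability mass toward higher (more threatened)
categories.  Parameters are estimated by maximum likelihood: BFGS on an
order-preserving re-parameterization of the thresholds, followed by
Newton polishing in the natural parameterization until the gradient
∞-norm drops below 1e-8.  Standard errors come from the inverse
observed information at the optimum; z = β̂/SE and p = 2·Φ(−|z|)
(two-sided Wald).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "STATUS_SCALE",
    "encode_status",
    "OrdinalFitResult",
    "fit_proportional_odds",
    "fit_trait_block",
]

#: IUCN red-list categories on the ordinal extinction-risk scale
STATUS_SCALE = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}

GRAD_TOL = 1e-8


class UnsupportedCategoryError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def encode_status(category: str) -> int:
    """Map a red-list code to its ordinal value (LC→0 … CR→4).

    Codes outside the five-point threat scale (DD, NE, RE, …) are not
    orderable and raise; such species must be excluded upstream.
    """
    code = str(category).strip().upper()
    if code not in STATUS_SCALE:
        raise UnsupportedCategoryError(
            f"red-list code {category!r} is not on the LC<NT<VU<EN<CR scale")
    return STATUS_SCALE[code]


@dataclass
class OrdinalFitResult:
    """MLE of a proportional-odds model (one component block of the risk model)."""

    names: list[str]
    coef: np.ndarray
    std_error: np.ndarray
    z_value: np.ndarray
    p_value: np.ndarray
    zeta: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    converged: bool
    messages: list[str] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.coef,
                             "std_error": self.std_error,
                             "z_value": self.z_value,
                             "p_value": self.p_value},
                            index=pd.Index(self.names, name="predictor"))


def _loglik_grad(beta: np.ndarray, zeta: np.ndarray, X: np.ndarray,
                 y: np.ndarray, K: int):
    """Log-likelihood and gradient in the natural (β, ζ) parameterization."""
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    zl = np.concatenate(([-np.inf], zeta))[y]        # ζ_{y-1}
    zu = np.concatenate((zeta, [np.inf]))[y]         # ζ_y
    Fu = expit(zu - eta)
    Fl = expit(zl - eta)
    prob = np.clip(Fu - Fl, 1e-300, None)
    ll = float(np.sum(np.log(prob)))

    fu = Fu * (1.0 - Fu)
    fl = Fl * (1.0 - Fl)
    dl_deta = (fl - fu) / prob
    g_beta = X.T @ dl_deta if p else np.zeros(0)
    g_zeta = np.zeros(K - 1)
    w_u = fu / prob
    w_l = fl / prob
    for k in range(K - 1):
        g_zeta[k] = np.sum(w_u[y == k]) - np.sum(w_l[y == k + 1])
    return ll, g_beta, g_zeta


def _zeta_to_theta(zeta: np.ndarray) -> np.ndarray:
    d = np.diff(zeta)
    return np.concatenate(([zeta[0]], np.log(d))) if len(zeta) > 1 \
        else zeta.copy()


def _theta_to_zeta(t: np.ndarray) -> np.ndarray:
    if len(t) == 1:
        return t.copy()
    return t[0] + np.concatenate(([0.0], np.cumsum(np.exp(t[1:]))))


def _numeric_hessian(beta, zeta, X, y, K, h=1e-5):
    """Central finite differences of the analytic gradient."""
    p = len(beta)
    m = p + K - 1
    H = np.zeros((m, m))
    theta = np.concatenate((beta, zeta))

    def grad_at(th):
        _, gb, gz = _loglik_grad(th[:p], th[p:], X, y, K)
        return np.concatenate((gb, gz))

    for j in range(m):
        step = np.zeros(m)
        step[j] = h
        H[:, j] = (grad_at(theta + step) - grad_at(theta - step)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_proportional_odds(X, y, names: list[str] | None = None,
                          *, max_iter: int = 500) -> OrdinalFitResult:
    """Fit P(Y ≤ k) = logistic(ζ_k − xβ) by maximum likelihood.

    ``X`` is an n×p design (DataFrame or array; no intercept column —
    the thresholds play that role) and ``y`` an integer ordinal response.
    Categories absent from the data are collapsed out of the threshold
    vector with a warning.  Raises :class:`ConvergenceError` with the
    gradient norm and the worst predictor on failure, and a singularity
    error when the observed information cannot be inverted.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and np.ndim(y) == 1 and len(np.ravel(y)) != 1:
            X = X.T
    y = np.asarray(pd.Series(y).to_numpy(), dtype=int)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.isnan(X).any() or pd.isna(y).any():
        raise ValueError("missing values in design or response")
    if len(y) != n:
        raise ValueError("X and y length mismatch")

    levels = np.unique(y)
    K = len(levels)
    if K < 2:
        raise ValueError("response uses fewer than 2 categories")
    messages: list[str] = []
    if not np.array_equal(levels, np.arange(levels.max() + 1)):
        messages.append(
            f"collapsed unused categories; observed levels {levels.tolist()}")
        warnings.warn(messages[-1], stacklevel=2)
    y = np.searchsorted(levels, y)
    if n <= p + K - 1:
        raise ValueError("too few observations for the parameter count")
    sd = X.std(axis=0)
    zero_var = [names[j] for j in np.flatnonzero(sd == 0)]
    if zero_var:
        raise np.linalg.LinAlgError(
            f"singular design: constant predictor(s) {zero_var}")

    # intercept-only start: ζ_k = logit of cumulative category frequency
    cumfreq = np.cumsum(np.bincount(y, minlength=K))[:-1] / n
    zeta0 = np.log(cumfreq / (1.0 - cumfreq))
    loglik_null, _, _ = _loglik_grad(np.zeros(p), zeta0, np.zeros((n, 0))
                                     if p == 0 else np.zeros((n, p)), y, K)

    def negll_theta(t):
        beta, zeta = t[:p], _theta_to_zeta(t[p:])
        ll, gb, gz = _loglik_grad(beta, zeta, X, y, K)
        # chain rule into the (ζ₁, log-increment) parameterization
        gt = np.empty(K - 1)
        gt[0] = gz.sum()
        if K > 2:
            rev = np.cumsum(gz[::-1])[::-1]
            gt[1:] = np.exp(t[p + 1:]) * rev[1:]
        return -ll, -np.concatenate((gb, gt))

    t0 = np.concatenate((np.zeros(p), _zeta_to_theta(zeta0)))
    res = minimize(negll_theta, t0, jac=True, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": max_iter})
    beta, zeta = res.x[:p], _theta_to_zeta(res.x[p:])

    # Newton polish in the natural parameterization
    for _ in range(50):
        ll, gb, gz = _loglik_grad(beta, zeta, X, y, K)
        g = np.concatenate((gb, gz))
        if np.max(np.abs(g)) < GRAD_TOL:
            break
        H = _numeric_hessian(beta, zeta, X, y, K)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        bn, zn = beta - step[:p], zeta - step[p:]
        if np.any(np.diff(zn) <= 0):
            break
        ll_new, _, _ = _loglik_grad(bn, zn, X, y, K)
        if not np.isfinite(ll_new) or ll_new < ll - 1e-9:
            break
        beta, zeta = bn, zn

    ll, gb, gz = _loglik_grad(beta, zeta, X, y, K)
    g = np.concatenate((gb, gz))
    gnorm = float(np.max(np.abs(g)))
    if ll > -1e-6:
        # every observation predicted with probability ~1: the MLE is at
        # infinity and Wald standard errors are meaningless
        worst = int(np.argmax(np.abs(beta))) if p else -1
        raise ConvergenceError(
            "perfect separation: the likelihood saturates "
            f"(loglik {ll:.2e}); offending predictor: "
            f"{names[worst] if worst >= 0 else 'thresholds'}")
    converged = gnorm < 1e-6
    if not converged:
        worst = int(np.argmax(np.abs(gb))) if p else -1
        raise ConvergenceError(
            f"optimizer did not converge (gradient inf-norm {gnorm:.2e}); "
            f"worst predictor: {names[worst] if worst >= 0 else 'thresholds'}"
            " — possible separation")

    info = -_numeric_hessian(beta, zeta, X, y, K)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular observed information matrix") from exc
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))
    return OrdinalFitResult(names=list(names), coef=beta, std_error=se,
                            z_value=z, p_value=pvals, zeta=zeta,
                            loglik=float(ll), loglik_null=float(loglik_null),
                            n=n, converged=bool(gnorm < GRAD_TOL * 10),
                            messages=messages)


def fit_trait_block(traits: pd.DataFrame, status, *, joint: bool = True):
    """Fit the four-trait extinction-risk block for one component.

    ``traits`` holds the predictors (body volume, wing area, color
    lightness, range size — one component's values), ``status`` the
    ordinal response.  By default all four predictors enter one joint
    model, so each effect is controlled for the others (in particular
    for range size); ``joint=False`` instead fits one single-predictor
    model per trait and returns a dict of results.
    """
    status = pd.Series(status)
    if isinstance(traits, pd.DataFrame) and isinstance(status.index,
                                                       pd.Index):
        if set(traits.index) == set(status.index):
            status = status.loc[traits.index]
    y = status.to_numpy()
    if joint:
        return fit_proportional_odds(traits, y)
    return {c: fit_proportional_odds(traits[[c]], y)
            for c in traits.columns}
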
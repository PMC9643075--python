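"""Phylogenetic mixed model: decomposition into P- and S-components.

The model is y = μ·1 + a + e with heritable values a ~ MVN(0, σ²ₐ G)
and independent residuals e ~ MVN(0, σ²ₑ I), where G is the tree's
covariance matrix normalized to unit depth so that σ²ₐ and σ²ₑ share
units.  Estimation profiles the phylogenetic heritability
h² = σ²ₐ / (σ²ₐ + σ²ₑ) over [0, 1]: at fixed h², V(h²) = h²G + (1−h²)I
yields closed-form GLS estimates of μ and the total variance, so the
ML problem is one-dimensional.  Given the fitted variance components,
the additive values are predicted by BLUP,

    â = σ̂²ₐ G (σ̂²ₐ G + σ̂²ₑ I)⁻¹ (y − μ̂ 1),

and the trait splits exactly into a phylogenetically predicted part
P = μ̂ + â and a species-specific residual S = y − P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .signal import (PROFILE_GRID_SIZE, PROFILE_TOL, PhyloCovariance,
                     PhyloSignalResult, _align_trait, _gls_profile,
                     phylo_covariance)

__all__ = ["DecompositionResult", "fit_lynch", "decompose_all"]


@dataclass
class DecompositionResult:
    """Variance components and the P/S split for one trait."""

    mu_hat: float
    sigma2_a_hat: float
    sigma2_e_hat: float
    P: pd.Series  # phylogenetically predicted part, μ̂ + â
    S: pd.Series  # species-specific residual, y − P
    loglik: float
    flags: list[str] = field(default_factory=list)

    @property
    def h2(self) -> float:
        tot = self.sigma2_a_hat + self.sigma2_e_hat
        return self.sigma2_a_hat / tot if tot > 0 else 0.0


def _profile_loglik_h2(y: np.ndarray, G: np.ndarray, h2: float):
    n = y.shape[0]
    V = h2 * G + (1.0 - h2) * np.eye(n)
    return _gls_profile(y, V)


def fit_lynch(y, tree_or_cov, *, grid_size: int = PROFILE_GRID_SIZE,
              tol: float = PROFILE_TOL) -> DecompositionResult:
    """Fit the phylogenetic mixed model to one trait by ML.

    ``y`` may be a pandas Series (aligned by tip label) or an array in
    the covariance's taxon order.  On a star phylogeny G = I and h² is
    unidentifiable; the h² = 0 solution is returned with a flag.
    """
    cov = (tree_or_cov if isinstance(tree_or_cov, PhyloCovariance)
           else phylo_covariance(tree_or_cov))
    yv = _align_trait(y, cov)
    n = cov.n
    G = cov.correlation()

    flags: list[str] = []
    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([_profile_loglik_h2(yv, G, g)[0] for g in grid])
    if not np.any(np.isfinite(lls)):
        raise ValueError("degenerate trait: zero variance")
    finite = lls[np.isfinite(lls)]
    if finite.max() - finite.min() < 1e-8:
        flags.append("non-identifiable")
        h2_hat, ll_hat = 0.0, float(lls[0])
    else:
        best = int(np.nanargmax(lls))
        h2_hat, ll_hat = float(grid[best]), float(lls[best])
        lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, grid_size - 1)]
        res = minimize_scalar(lambda g: -_profile_loglik_h2(yv, G, g)[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": tol})
        if np.isfinite(res.fun) and -res.fun > ll_hat:
            h2_hat, ll_hat = float(res.x), float(-res.fun)

    ll, mu_hat, s2_tot = _profile_loglik_h2(yv, G, h2_hat)
    sigma2_a = h2_hat * s2_tot
    sigma2_e = (1.0 - h2_hat) * s2_tot
    r = yv - mu_hat
    if h2_hat > 0.0:
        V = h2_hat * G + (1.0 - h2_hat) * np.eye(n)
        a_hat = h2_hat * (G @ np.linalg.solve(V, r))
    else:
        a_hat = np.zeros(n)

    idx = pd.Index(cov.taxa, name="species")
    P = pd.Series(mu_hat + a_hat, index=idx, name="P")
    S = pd.Series(yv - P.to_numpy(), index=idx, name="S")
    return DecompositionResult(mu_hat=float(mu_hat),
                               sigma2_a_hat=float(sigma2_a),
                               sigma2_e_hat=float(sigma2_e),
                               P=P, S=S, loglik=float(ll_hat), flags=flags)


def decompose_all(traits: pd.DataFrame, tree_or_cov,
                  trait_names: list[str] | None = None, *,
                  signal_results: dict[str, PhyloSignalResult] | None = None,
                  gate_alpha: float = 0.05):
    """Decompose every named trait into P- and S-components.

    When ``signal_results`` is supplied, only traits whose phylogenetic
    signal is significant at ``gate_alpha`` are decomposed (the others
    are reported as skipped); otherwise all traits are decomposed.

    Returns ``(results, P_matrix, S_matrix, skipped)`` where the
    matrices are species × trait DataFrames aligned to the tree's
    taxon order.
    """
    cov = (tree_or_cov if isinstance(tree_or_cov, PhyloCovariance)
           else phylo_covariance(tree_or_cov))
    if trait_names is None:
        trait_names = list(traits.columns)
    missing_cols = [t for t in trait_names if t not in traits.columns]
    if missing_cols:
        raise ValueError(f"traits absent from table: {missing_cols}")
    na_counts = traits[trait_names].isna().sum()
    bad = na_counts[na_counts > 0]
    if len(bad):
        raise ValueError(
            "missing trait values: "
            + ", ".join(f"{t} ({c} missing)" for t, c in bad.items()))

    results: dict[str, DecompositionResult] = {}
    skipped: list[str] = []
    for name in trait_names:
        if signal_results is not None:
            sig = signal_results[name]
            if sig.p_value >= gate_alpha:
                skipped.append(name)
                continue
        results[name] = fit_lynch(traits[name], cov)

    idx = pd.Index(cov.taxa, name="species")
    P = pd.DataFrame({t: r.P for t, r in results.items()}, index=idx)
    S = pd.DataFrame({t: r.S for t, r in results.items()}, index=idx)
    return results, P, S, skipped


def variance_components_table(results: dict[str, DecompositionResult]
                              ) -> pd.DataFrame:
    rows = [{"trait": t, "mu": r.mu_hat, "sigma2_a": r.sigma2_a_hat,
             "sigma2_e": r.sigma2_e_hat, "h2": r.h2, "loglik": r.loglik,
             "flags": ";".join(r.flags)} for t, r in results.items()]
    return pd.DataFrame(rows)
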
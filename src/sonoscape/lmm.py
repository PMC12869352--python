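"""Fast maximum-likelihood random-intercept models for all-subsets selection.

The acoustic-space selection stage fits, for every minute of the day, all
2^7 = 128 fixed-effect subsets of a linear mixed model with a random
intercept for recorder hardware.  That is on the order of 10^5 small fits
per dataset, so this module implements the random-intercept ML fit
directly via the profiled likelihood instead of calling a general mixed-
model package per candidate:

with V(λ) = I + λ Z Zᵀ (λ = τ²/σ², Z the group indicator), the fixed
effects and residual variance have closed forms given λ, so

    ℓ_profile(λ) = -n/2 [log(2π σ̂²(λ)) + 1] - ½ log|V(λ)|.

λ is maximized over a fixed grid that includes the λ = 0 boundary
(singular fits — a zero hardware variance — are accepted, merely noted).
For each grid point the whitening of y and the full design matrix is
shared across all candidate subsets, which then only need tiny
normal-equation solves.  Tests cross-check the likelihood against the
closed-form multivariate-normal density and the subset selection against
statsmodels' MixedLM.

AIC is -2ℓ + 2(p + 2): p fixed-effect coefficients plus the two variance
parameters, matching the convention of statsmodels' MixedLM under ML.
ML (not REML) is used throughout because AIC comparisons across different
fixed-effect structures are invalid under REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, solve_triangular

logger = logging.getLogger(__name__)

#: λ grid for the profiled likelihood; includes the boundary λ = 0.
DEFAULT_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-4.0, 3.0, 57)])


@dataclass
class SubsetFit:
    """One candidate fit: subset index, log-likelihood, AIC, variance ratio."""

    subset: tuple[int, ...]
    loglik: float
    aic: float
    lam: float
    n_params: int
    converged: bool = True


def _whiten(y: np.ndarray, x: np.ndarray, zzt: np.ndarray, lam: float):
    """Whitened (L⁻¹y, L⁻¹X) and log|V| for V = I + λ Z Zᵀ = L Lᵀ."""
    n = y.shape[0]
    if lam == 0.0:
        return y, x, 0.0
    c, _ = cho_factor(np.eye(n) + lam * zzt, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    lw = solve_triangular(c, np.column_stack([y, x]), lower=True)
    return lw[:, 0], lw[:, 1:], logdet


def profiled_loglik(y: np.ndarray, x: np.ndarray, groups: np.ndarray,
                    lam: float) -> tuple[float, np.ndarray, float]:
    """Profiled ML log-likelihood at variance ratio ``lam``.

    Returns (loglik, beta_hat, sigma2_hat) for the model
    y ~ N(Xβ, σ²(I + λ Z Zᵀ)).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    z = _indicator(groups)
    yw, xw, logdet = _whiten(y, x, z @ z.T, lam)
    n = y.shape[0]
    beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
    return ll, beta, sigma2


def _indicator(groups) -> np.ndarray:
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    z = np.zeros((groups.shape[0], levels.shape[0]))
    z[np.arange(groups.shape[0]), codes] = 1.0
    return z


def fit_all_subsets(y: np.ndarray, x_full: np.ndarray, groups: np.ndarray,
                    subsets: list[tuple[int, ...]],
                    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                    always_cols: tuple[int, ...] = (0,)) -> list[SubsetFit]:
    """ML-fit every column subset of ``x_full`` with a shared random intercept.

    ``subsets`` are tuples of column indices into ``x_full``; ``always_cols``
    (the intercept) are prepended to each.  Returns one :class:`SubsetFit`
    per subset; candidates whose normal equations are numerically singular
    at every grid point are marked unconverged.
    """
    y = np.asarray(y, dtype=np.float64)
    x_full = np.asarray(x_full, dtype=np.float64)
    n = y.shape[0]
    z = _indicator(groups)
    zzt = z @ z.T
    eye = np.eye(n)
    col_sets = [tuple(always_cols) + tuple(s) for s in subsets]
    best_ll = np.full(len(col_sets), -np.inf)
    best_lam = np.zeros(len(col_sets))
    ever_ok = np.zeros(len(col_sets), dtype=bool)

    for lam in lambda_grid:
        if lam == 0.0:
            yw, xw, logdet = y, x_full, 0.0
        else:
            c, _ = cho_factor(eye + lam * zzt, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            lw = solve_triangular(c, np.column_stack([y, x_full]), lower=True)
            yw, xw = lw[:, 0], lw[:, 1:]
        g = xw.T @ xw
        c_vec = xw.T @ yw
        yy = float(yw @ yw)
        for si, cols in enumerate(col_sets):
            gi = g[np.ix_(cols, cols)]
            ci = c_vec[list(cols)]
            try:
                beta = np.linalg.solve(gi, ci)
            except np.linalg.LinAlgError:
                continue
            rss = max(yy - float(ci @ beta), 1e-12)
            sigma2 = rss / n
            ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
            ever_ok[si] = True
            if ll > best_ll[si]:
                best_ll[si] = ll
                best_lam[si] = lam

    fits = []
    for si, (cols, s) in enumerate(zip(col_sets, subsets)):
        p = len(cols)
        if not ever_ok[si]:
            fits.append(SubsetFit(subset=tuple(s), loglik=np.nan, aic=np.inf,
                                  lam=np.nan, n_params=p, converged=False))
            continue
        aic = -2.0 * best_ll[si] + 2.0 * (p + 2)
        fits.append(SubsetFit(subset=tuple(s), loglik=float(best_ll[si]),
                              aic=float(aic), lam=float(best_lam[si]),
                              n_params=p))
    return fits
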
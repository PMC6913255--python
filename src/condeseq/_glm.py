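"""Vectorised negative-binomial GLM fitting shared by the DE engines and RUVr.

All routines operate on the full genes x samples count matrix at once.  The
design matrix is common to every gene, so the IRLS normal equations are
batched: weights are a (G, n) array, X^T W X a stacked (G, p, p) array solved
with one batched ``np.linalg.solve``.  Dispersion estimation evaluates the
Cox-Reid adjusted profile log-likelihood on a grid of dispersions, reusing
these batched fits, and locates per-gene maxima by parabolic interpolation
on the log-dispersion grid.

Parametrisation: Var(Y) = mu + phi * mu^2 with phi >= 0 (phi = 0 is the
Poisson limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

MIN_MU = 1e-10
ETA_MAX = 50.0  # keeps exp(eta) finite in float64
MIN_PHI = 1e-8
MAX_PHI = 10.0
MAX_ITER = 100
DEV_TOL = 1e-8
RIDGE = 1e-10

_POISSON_PHI = 1e-10  # below this, use Poisson formulas


def nb_unit_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-observation NB deviance; ``phi`` broadcasts over (G, n)."""
    mu = np.maximum(mu, MIN_MU)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.maximum(y, MIN_MU) / mu), 0.0)
    phi = np.asarray(phi, dtype=float)
    pois = 2.0 * (t1 - (y - mu))
    r = 1.0 / np.maximum(phi, _POISSON_PHI)
    t2 = (y + r) * np.log((y + r) / (mu + r))
    nb = 2.0 * (t1 - t2)
    return np.where(phi > _POISSON_PHI, nb, pois)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples."""
    mu = np.maximum(mu, MIN_MU)
    phi = np.asarray(phi, dtype=float)
    r = 1.0 / np.maximum(phi, _POISSON_PHI)
    nb = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    return np.where(np.broadcast_to(phi, nb.shape) > _POISSON_PHI, nb, pois).sum(axis=-1)


@dataclass
class GLMFit:
    beta: np.ndarray        # (G, p), natural-log scale
    mu: np.ndarray          # (G, n)
    deviance: np.ndarray    # (G,)
    converged: np.ndarray   # (G,) bool
    xtwx: np.ndarray        # (G, p, p) at the final weights


def _phi_col(phi, n_genes: int) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(n_genes, float(phi))
    return phi.reshape(-1, 1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi,
    max_iter: int = MAX_ITER,
    tol: float = DEV_TOL,
) -> GLMFit:
    """IRLS fit of log-linear NB GLMs for all genes simultaneously.

    ``y`` is (G, n), ``X`` (n, p) shared across genes, ``offset`` (n,) or
    (G, n) on the natural-log scale, ``phi`` a scalar or (G,) dispersion.
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))
    phi = _phi_col(phi, G)

    mu = np.maximum((y + y.mean(axis=1, keepdims=True)) / 2.0, 0.1)
    eta = np.log(mu)
    dev = nb_unit_deviance(y, mu, phi).sum(axis=1)
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p)

    beta = np.zeros((G, p))
    xtwx = np.empty((G, p, p))
    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = (eta - off) + (y - mu) / mu
        xtwx = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True) + RIDGE * eye
        xtwz = np.einsum("gn,ni->gi", w * z, X, optimize=True)
        beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + off, -ETA_MAX, ETA_MAX)
        mu = np.maximum(np.exp(eta), MIN_MU)
        dev_new = nb_unit_deviance(y, mu, phi).sum(axis=1)
        rel = np.abs(dev_new - dev) / (np.abs(dev) + 0.1)
        dev = dev_new
        converged = rel < tol
        if converged.all():
            break
    # final-weight information matrix (used for Cox-Reid and Wald SEs)
    w = mu / (1.0 + phi * mu)
    xtwx = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True) + RIDGE * eye
    return GLMFit(beta=beta, mu=mu, deviance=dev, converged=converged, xtwx=xtwx)


def adjusted_profile_loglik(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion(s) phi."""
    fit = fit_nb_glm(y, X, offset, phi)
    phi_c = _phi_col(phi, y.shape[0])
    ll = nb_loglik(y, fit.mu, phi_c)
    _, logdet = np.linalg.slogdet(fit.xtwx)
    return ll - 0.5 * logdet


def apl_grid(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phis: np.ndarray
) -> np.ndarray:
    """(G, K) matrix of adjusted profile log-likelihoods over a phi grid."""
    return np.column_stack(
        [adjusted_profile_loglik(y, X, offset, float(phi)) for phi in phis]
    )


def interp_argmax(log_grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-row argmax on a 1-D grid, refined by parabolic interpolation.

    ``log_grid`` is the (K,) grid coordinate (log-dispersion), ``values`` a
    (G, K) matrix of objective values.  Interior maxima are refined through
    the vertex of the parabola fitted to the three neighbouring points;
    boundary maxima return the boundary coordinate.
    """
    values = np.atleast_2d(values)
    k = values.shape[1]
    idx = np.argmax(values, axis=1)
    out = log_grid[idx].astype(float)
    interior = (idx > 0) & (idx < k - 1)
    if interior.any():
        i = idx[interior]
        rows = np.where(interior)[0]
        x0, x1, x2 = log_grid[i - 1], log_grid[i], log_grid[i + 1]
        y0 = values[rows, i - 1]
        y1 = values[rows, i]
        y2 = values[rows, i + 1]
        denom = y0 - 2.0 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (y0 - y2) / denom
        shift = np.where(np.abs(denom) > 1e-12, shift, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        # uniform grid assumed: step from the local spacing
        step = (x2 - x0) / 2.0
        out[rows] = x1 + shift * step
    return out


def deviance_residuals(
    y: np.ndarray, mu: np.ndarray, phi
) -> np.ndarray:
    phi = _phi_col(phi, y.shape[0])
    unit = nb_unit_deviance(y, mu, phi)
    return np.sign(y - mu) * np.sqrt(np.maximum(unit, 0.0))
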
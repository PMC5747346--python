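"""Dispersion estimation by Cox-Reid adjusted profile likelihood.

The adjusted profile log-likelihood for locus g at dispersion phi is

    APL_g(phi) = loglik(y_g; mu_hat_g(phi), phi) - 0.5 log det(X' W X)

where mu_hat_g(phi) is the maximum-likelihood fit at that dispersion and
W = diag(mu / (1 + phi mu)) are the working weights; the determinant
term is the Cox-Reid adjustment for estimating the coefficients.  The
common dispersion maximizes the sum of APL_g over loci; locus-wise
(tagwise) dispersions maximize a weighted likelihood

    APL_g(phi) + prior_n * mean_g APL_g(phi)

where prior_n = prior_df / residual_df is the weight (in loci
equivalents) given to the shared curve.  No abundance trend is fitted:
BS-seq data show no apparent mean-dispersion relationship.

When not supplied, the prior degrees of freedom are estimated by a
method-of-moments comparison of the per-locus APL score statistics at
the common dispersion with their expected sampling spread: writing
s_g and I_g for the first and (negated) second derivatives of APL_g with
respect to log phi at the common maximum, homogeneity implies
E[s_g^2] ~= I_g, while genuine dispersion heterogeneity with variance
tau^2 on the log scale inflates this to I_g + tau^2 I_g^2.  Hence

    tau^2_hat = max(0, (sum_g s_g^2 - sum_g I_g) / sum_g I_g^2)

and the prior weight matching a prior precision of 1/tau^2 is
prior_n = 1 / (tau^2 * mean I_g), giving prior_df = prior_n * residual_df.
tau^2 = 0 maps to prior_df = inf, i.e. all tagwise dispersions equal the
common value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ObservationDesign
from .glm import _fit_glm, nb_loglik

__all__ = [
    "DispersionEstimate",
    "default_grid",
    "apl_matrix",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "estimate_dispersion",
]

# fitted means are floored in the Cox-Reid information matrix so that a
# block of exactly-zero fitted values (all-Me or all-Un loci) cannot make
# the determinant vanish; the floor is constant in phi so it does not
# move the maximizer
_CR_MU_FLOOR = 1e-4


def default_grid(low: float = 1e-4, high: float = 10.0, n: int = 31) -> np.ndarray:
    """Log-spaced dispersion grid used for profile maximization."""
    return np.exp(np.linspace(np.log(low), np.log(high), n))


def _design_matrix(design) -> np.ndarray:
    return design.matrix if isinstance(design, ObservationDesign) else np.asarray(design, dtype=float)


def apl_matrix(counts, design, offsets, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Cox-Reid adjusted profile log-likelihood per locus per grid point.

    Returns ``(apl, grid)`` with ``apl`` of shape (n_loci, len(grid)).
    Fits are warm-started along the grid.
    """
    X = _design_matrix(design)
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    G = y.shape[0]
    p = X.shape[1]
    apl = np.empty((G, len(grid)))
    beta = None
    for k, phi in enumerate(grid):
        beta, mu, _, _ = _fit_glm(y, X, offsets, phi, beta_init=beta)
        ll = nb_loglik(y, mu, np.full(G, phi))
        mu_cr = np.maximum(mu, _CR_MU_FLOOR)
        w = mu_cr / (1.0 + phi * mu_cr)
        info = np.einsum("gm,mp,mq->gpq", w, X, X, optimize=True)
        sign, logdet = np.linalg.slogdet(info)
        bad = sign <= 0
        if bad.any():  # numerically singular despite the floor
            ib = info[bad]
            ridge = 1e-8 * (1.0 + np.trace(ib, axis1=1, axis2=2) / p)
            ib[:, np.arange(p), np.arange(p)] += ridge[:, None]
            _, logdet[bad] = np.linalg.slogdet(ib)
        apl[:, k] = ll - 0.5 * logdet
    return apl, grid


def _interp_max(values: np.ndarray, log_grid: np.ndarray):
    """Vectorized quadratic interpolation of per-row grid maximizers."""
    values = np.atleast_2d(values)
    idx = np.argmax(values, axis=1)
    out = log_grid[idx]
    interior = (idx > 0) & (idx < len(log_grid) - 1)
    if interior.any():
        i = idx[interior]
        rows = np.flatnonzero(interior)
        y0 = values[rows, i - 1]
        y1 = values[rows, i]
        y2 = values[rows, i + 1]
        h = log_grid[1] - log_grid[0]
        denom = y0 - 2.0 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (y0 - y2) / denom
        delta = np.where(np.isfinite(delta), np.clip(delta, -1.0, 1.0), 0.0)
        out[rows] = log_grid[i] + delta * h
    return out


def estimate_common_dispersion(counts, design, offsets, grid=None, apl=None) -> float:
    """Dispersion maximizing the summed Cox-Reid APL over all loci."""
    y = np.atleast_2d(np.asarray(counts))
    if not np.any(y.sum(axis=1) > 0):
        raise ValueError("cannot estimate dispersion from all-zero counts")
    if apl is None:
        apl, grid = apl_matrix(counts, design, offsets, grid)
    else:
        grid = np.asarray(grid if grid is not None else default_grid(), dtype=float)
    total = apl.sum(axis=0)
    log_common = _interp_max(total[None, :], np.log(grid))[0]
    return float(np.exp(log_common))


@dataclass
class DispersionEstimate:
    """Common and empirical-Bayes moderated locus-wise dispersions."""

    common: float
    tagwise: np.ndarray
    prior_df: float


def _estimate_prior_df(apl: np.ndarray, grid: np.ndarray, common: float, residual_df: float) -> float:
    log_grid = np.log(grid)
    h = log_grid[1] - log_grid[0]
    j = int(np.clip(np.searchsorted(log_grid, np.log(common)), 1, len(grid) - 2))
    score = (apl[:, j + 1] - apl[:, j - 1]) / (2.0 * h)
    info = -(apl[:, j + 1] - 2.0 * apl[:, j] + apl[:, j - 1]) / h**2
    ok = np.isfinite(score) & np.isfinite(info) & (info > 0)
    if ok.sum() < 2:
        return np.inf
    s2 = score[ok] ** 2
    info = info[ok]
    tau2 = (s2.sum() - info.sum()) / (info**2).sum()
    if tau2 <= 0:
        return np.inf
    prior_n = 1.0 / (tau2 * info.mean())
    return float(prior_n * residual_df)


def estimate_tagwise_dispersion(
    counts, design, offsets, common: float, prior_df: float | None = None, grid=None, apl=None
) -> DispersionEstimate:
    """Empirical-Bayes moderated locus-wise dispersions.

    Maximizes APL_g + prior_n * mean(APL) per locus, with
    prior_n = prior_df / residual_df.  ``prior_df=None`` estimates the
    prior degrees of freedom from the data (see module docstring);
    ``prior_df=inf`` returns the common dispersion for every locus.
    """
    if common <= 0:
        raise ValueError("common dispersion must be positive")
    X = _design_matrix(design)
    y = np.atleast_2d(np.asarray(counts))
    if apl is None:
        apl, grid = apl_matrix(counts, design, offsets, grid)
    else:
        grid = np.asarray(grid if grid is not None else default_grid(), dtype=float)
    G = y.shape[0]
    residual_df = y.shape[1] - X.shape[1]
    if residual_df < 1:
        raise ValueError("tagwise estimation requires positive residual df")

    if prior_df is None:
        prior_df = _estimate_prior_df(apl, grid, common, residual_df)

    if np.isinf(prior_df):
        return DispersionEstimate(common=common, tagwise=np.full(G, common), prior_df=np.inf)

    prior_n = prior_df / residual_df
    weighted = apl + prior_n * apl.mean(axis=0)[None, :]
    log_tag = _interp_max(weighted, np.log(grid))
    return DispersionEstimate(common=common, tagwise=np.exp(log_tag), prior_df=float(prior_df))


def estimate_dispersion(counts, design, offsets, grid=None, prior_df=None) -> DispersionEstimate:
    """Convenience wrapper: common + tagwise estimation sharing one APL pass."""
    apl, grid = apl_matrix(counts, design, offsets, grid)
    common = estimate_common_dispersion(counts, design, offsets, grid=grid, apl=apl)
    return estimate_tagwise_dispersion(
        counts, design, offsets, common, prior_df=prior_df, grid=grid, apl=apl
    )
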
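"""Negative-binomial GLMs with offsets, likelihood-ratio contrast tests
and FDR control.

Each locus g contributes a vector of counts y_gi (two per sample: Me and
Un) modeled as NB with mean mu_gi and dispersion phi_g, where

    log mu_gi = sum_j x_ij beta_gj + log N_i

with x the observation-level design, beta the per-locus coefficients and
N_i the effective library size of column i (library size times
normalization factor).  The variance function is var = mu + phi mu^2;
phi = 0 degenerates to Poisson, in which case a likelihood-ratio test on
the condition block is exactly a binomial logistic-regression deviance
test because inference conditions on per-sample totals.

Fitting uses damped Fisher scoring on the log link, vectorized across
loci (all loci share one design matrix, so the per-locus normal
equations are solved as a batched p x p system).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import ObservationDesign, make_contrast

__all__ = [
    "NBGLMFit",
    "DMTestResult",
    "fit",
    "lrt",
    "ave_log_cpm",
    "benjamini_hochberg",
    "decide_tests",
    "top_tags",
    "nb_deviance",
    "nb_loglik",
]

_MIN_MU = 1e-300


def nb_deviance(y, mu, phi):
    """Residual NB deviance per locus (rows summed); phi scalar or per-locus."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MIN_MU)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    t1 = special.xlogy(y, y / mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(
            phi > 0,
            (y + 1.0 / np.where(phi > 0, phi, 1.0)) * (np.log1p(phi * y) - np.log1p(phi * mu)),
            y - mu,
        )
    return 2.0 * (t1 - t2).sum(axis=-1)


def nb_loglik(y, mu, phi):
    """NB log-likelihood per locus (rows summed); Poisson when phi == 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MIN_MU)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    if np.all(phi == 0):
        ll = special.xlogy(y, mu) - mu - special.gammaln(y + 1)
        return ll.sum(axis=-1)
    r = 1.0 / np.where(phi > 0, phi, 1.0)
    nb = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + special.xlogy(y, mu / (r + mu))
    )
    pois = special.xlogy(y, mu) - mu - special.gammaln(y + 1)
    return np.where(phi > 0, nb, pois).sum(axis=-1)


def _fit_glm(counts, X, offset, phi, beta_init=None, tol=1e-10, maxit=100):
    """Batched damped Fisher scoring for NB GLMs sharing one design.

    Parameters are per-locus; ``counts`` is (G, m), ``X`` is (m, p),
    ``offset`` is (m,) or (G, m), ``phi`` scalar or (G,).  Returns
    (beta, mu, deviance, converged).
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(X, dtype=float)
    G, m = y.shape
    p = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, m))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))[:, None]

    if beta_init is None:
        z0 = np.log(y + 0.125) - offset
        beta = z0 @ np.linalg.pinv(X).T
    else:
        beta = np.array(beta_init, dtype=float)

    def mu_of(beta):
        eta = np.clip(beta @ X.T + offset, -300.0, 300.0)
        return np.exp(eta)

    mu = mu_of(beta)
    dev = nb_deviance(y, mu, phi)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)

    for _ in range(maxit):
        if not active.any():
            break
        ya, mua, oa, pa = y[active], mu[active], offset[active], phi[active]
        w = np.maximum(mua / (1.0 + pa * mua), 1e-300)
        z = np.log(np.maximum(mua, _MIN_MU)) - oa + (ya - mua) / np.maximum(mua, _MIN_MU)
        A = np.einsum("gm,mp,mq->gpq", w, X, X, optimize=True)
        b = np.einsum("gm,mp->gp", w * z, X, optimize=True)
        # tiny ridge proportional to the trace guards exactly singular
        # information matrices (e.g. fitted means driven to zero)
        ridge = 1e-12 * np.trace(A, axis1=1, axis2=2) / p + 1e-300
        A[:, np.arange(p), np.arange(p)] += ridge[:, None]
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in zip(A, b)])

        old_beta = beta[active]
        beta_new = np.where(np.isfinite(beta_new), beta_new, old_beta)
        eta_new = np.clip(beta_new @ X.T + oa, -300.0, 300.0)
        mu_new = np.exp(eta_new)
        dev_new = nb_deviance(ya, mu_new, pa)

        # step halving where the deviance increased
        bad = dev_new > dev[active] * (1 + 1e-12) + 1e-12
        halvings = 0
        while bad.any() and halvings < 40:
            beta_new[bad] = 0.5 * (beta_new[bad] + old_beta[bad])
            eta_bad = np.clip(beta_new[bad] @ X.T + oa[bad], -300.0, 300.0)
            mu_new[bad] = np.exp(eta_bad)
            dev_new[bad] = nb_deviance(ya[bad], mu_new[bad], pa[bad])
            bad = dev_new > dev[active] * (1 + 1e-12) + 1e-12
            halvings += 1

        done = np.abs(dev[active] - dev_new) < tol * (np.abs(dev_new) + 1.0)
        idx = np.flatnonzero(active)
        beta[idx] = beta_new
        mu[idx] = mu_new
        dev[idx] = dev_new
        converged[idx[done]] = True
        active[idx[done]] = False

    return beta, mu, dev, converged


def _effective_lib_sizes(lib_sizes, norm_factors, n_cols):
    lib = np.broadcast_to(np.asarray(lib_sizes, dtype=float), (n_cols,))
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    nf = np.ones(n_cols) if norm_factors is None else np.broadcast_to(np.asarray(norm_factors, dtype=float), (n_cols,))
    return lib * nf


@dataclass
class NBGLMFit:
    """Per-locus NB GLM fits for one observation-level design.

    ``coefficients`` hold the raw maximum-likelihood fit on the natural
    log scale (used for all deviances and LR statistics);
    ``reported_coefficients`` come from a second fit on prior-count
    augmented data and are on the log2 scale (used for reporting logFC).
    """

    coefficients: np.ndarray
    reported_coefficients: np.ndarray
    fitted_values: np.ndarray
    deviance: np.ndarray
    converged: np.ndarray
    design: ObservationDesign
    offsets: np.ndarray
    dispersion: np.ndarray
    counts: np.ndarray = field(repr=False)
    lib_sizes: np.ndarray = field(repr=False)
    genes: pd.DataFrame | None = field(default=None, repr=False)


def fit(
    counts,
    design: ObservationDesign,
    lib_sizes,
    norm_factors=None,
    dispersion=0.0,
    prior_count: float = 0.125,
    genes: pd.DataFrame | None = None,
) -> NBGLMFit:
    """Fit per-locus NB GLMs with offsets log(lib_size * norm_factor).

    A second fit on counts augmented by a library-size-scaled prior count
    (``prior_count * lib_i / mean(lib)`` added to each observation, with
    effective library sizes inflated by twice the scaled prior) provides
    finite, stabilized coefficients for reporting on the log2 scale.
    With equal library sizes this adds exactly ``prior_count`` to every
    count.  Raw (unaugmented) fits are used for all deviances.
    """
    counts = np.atleast_2d(np.asarray(counts))
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    X = design.matrix
    G, m = counts.shape
    if X.shape[0] != m:
        raise ValueError(f"design has {X.shape[0]} rows but counts have {m} columns")
    disp = np.asarray(dispersion, dtype=float)
    if np.any(disp < 0):
        raise ValueError("dispersion must be >= 0")

    lib = _effective_lib_sizes(lib_sizes, norm_factors, m)
    offset = np.log(lib)

    beta, mu, dev, conv = _fit_glm(counts, X, offset, disp)

    prior = prior_count * lib / lib.mean()
    lib_aug = lib + 2.0 * prior
    beta2, _, _, _ = _fit_glm(counts + prior, X, np.log(lib_aug), disp)

    return NBGLMFit(
        coefficients=beta,
        reported_coefficients=beta2 / np.log(2.0),
        fitted_values=mu,
        deviance=dev,
        converged=conv,
        design=design,
        offsets=offset,
        dispersion=np.broadcast_to(disp, (G,)).copy(),
        counts=counts,
        lib_sizes=lib,
        genes=genes.reset_index(drop=True) if genes is not None else None,
    )


@dataclass
class DMTestResult:
    """Per-locus differential methylation test results."""

    table: pd.DataFrame  # logFC, logCPM, LR, PValue, FDR (+ gene annotation)
    contrast: np.ndarray
    df: int

    def __len__(self) -> int:
        return len(self.table)


def _as_contrast_matrix(fit_obj: NBGLMFit, contrast) -> np.ndarray:
    design = fit_obj.design
    if isinstance(contrast, str):
        contrast = make_contrast(design.colnames, contrast)
    if isinstance(contrast, pd.DataFrame):
        contrast = contrast.to_numpy()
    C = np.asarray(contrast, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != len(design.colnames):
        raise ValueError("contrast length does not match number of design columns")
    if not np.any(C):
        raise ValueError("contrast must be non-zero")
    if np.any(C[design.sample_columns] != 0):
        raise ValueError("contrasts may not involve sample-coverage columns")
    return C


def lrt(fit_obj: NBGLMFit, contrast) -> DMTestResult:
    """Likelihood-ratio test of one or more contrasts on the condition block.

    The null model constrains ``contrast' beta = 0``: the design is
    re-expressed on a basis of the null space of the contrast matrix
    (computed by QR/SVD), the sample-coverage columns being unaffected
    because contrasts may not touch them.  LR is the deviance difference
    between null and full raw fits, chi-square with df = rank(contrast)
    under the null; logFC is the contrast applied to the reported (log2,
    prior-count augmented) coefficients; FDR is Benjamini-Hochberg.
    """
    from scipy.linalg import null_space

    C = _as_contrast_matrix(fit_obj, contrast)
    df = int(np.linalg.matrix_rank(C))
    B = null_space(C.T)
    X_null = fit_obj.design.matrix @ B

    beta0 = fit_obj.coefficients @ B  # projection as a warm start
    _, _, dev_null, _ = _fit_glm(
        fit_obj.counts, X_null, fit_obj.offsets, fit_obj.dispersion, beta_init=beta0
    )
    LR = np.maximum(dev_null - fit_obj.deviance, 0.0)
    pvalue = stats.chi2.sf(LR, df)
    logfc = fit_obj.reported_coefficients @ C

    table = pd.DataFrame(index=pd.RangeIndex(len(LR)))
    if fit_obj.genes is not None:
        for col in fit_obj.genes.columns:
            table[col] = fit_obj.genes[col].to_numpy()
    if logfc.shape[1] == 1:
        table["logFC"] = logfc[:, 0]
    else:
        for j in range(logfc.shape[1]):
            table[f"logFC.{j+1}"] = logfc[:, j]
    table["logCPM"] = ave_log_cpm(fit_obj.counts, fit_obj.lib_sizes)
    table["LR"] = LR
    table["PValue"] = pvalue
    table["FDR"] = benjamini_hochberg(pvalue)
    return DMTestResult(table=table, contrast=C, df=df)


def ave_log_cpm(counts, lib_sizes, prior: float = 2.0) -> np.ndarray:
    """Average log2 counts-per-million with a prior count.

    logCPM = log2( 1e6 * (mean count + prior) / (mean lib size + 2*prior) ).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    lib = np.asarray(lib_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    mean_count = counts.mean(axis=1)
    mean_lib = lib.mean()
    return np.log2(1e6 * (mean_count + prior) / (mean_lib + 2.0 * prior))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def decide_tests(result: DMTestResult, fdr: float = 0.05):
    """Classify each locus as -1 (down), 0 (not significant) or +1 (up).

    Returns (per-locus vector, summary Series with Down/NotSig/Up counts).
    """
    table = result.table
    sig = table["FDR"].to_numpy() <= fdr
    logfc = table["logFC"].to_numpy()
    calls = np.where(sig & (logfc > 0), 1, np.where(sig & (logfc < 0), -1, 0))
    summary = pd.Series(
        [(calls == -1).sum(), (calls == 0).sum(), (calls == 1).sum()],
        index=["Down", "NotSig", "Up"],
    )
    return calls, summary


def top_tags(result: DMTestResult, n: int | None = None, p_cutoff: float | None = None) -> pd.DataFrame:
    """Rank loci by PValue (ties by |logFC| descending) and truncate.

    ``p_cutoff`` filters on BH-adjusted FDR; ``n`` limits the number of
    rows returned.
    """
    table = result.table
    order = np.lexsort((-np.abs(table["logFC"].to_numpy()), table["PValue"].to_numpy()))
    ranked = table.iloc[order]
    if p_cutoff is not None:
        ranked = ranked[ranked["FDR"] <= p_cutoff]
    if n is not None:
        ranked = ranked.head(n)
    return ranked
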
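"""Self-contained directional gene-set tests and the methylation vs
expression correlation analysis.

The rotation test asks whether a pre-specified set of loci (a
chromosome's CpGs, or the differentially methylated genes weighted by
their methylation log-fold-changes) shows a coordinated shift for a
contrast.  Per-locus z-equivalent statistics are the signed square roots
of the likelihood-ratio statistics (signed by logFC), asymptotically
standard normal under the null.  The null distribution of the set
statistic is generated by random rotations of the z vector on its
sphere: a rotated vector is uniform on the sphere of radius ||z||, so
only the set's coordinates and an independent chi-square carrying the
remaining squared norm need to be sampled.  This keeps the test
self-contained — the effective scale of the null comes from the observed
||z|| rather than an assumed unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_logger = logging.getLogger(__name__)

from .glm import NBGLMFit, benjamini_hochberg, lrt

__all__ = [
    "WeightedGeneSet",
    "rotation_gene_set_test",
    "rotation_test_from_z",
    "regression_through_origin",
    "OriginRegression",
    "barcode_data",
    "signed_sqrt_lr",
]


@dataclass
class WeightedGeneSet:
    """A named set of row ids with optional per-member weights."""

    name: str
    ids: Sequence
    weights: Sequence[float] | None = None

    def __post_init__(self):
        ids = list(self.ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"gene set {self.name!r} contains duplicate ids")
        if self.weights is not None and len(list(self.weights)) != len(ids):
            raise ValueError(f"gene set {self.name!r}: weights must match ids")


def signed_sqrt_lr(table: pd.DataFrame) -> np.ndarray:
    """Per-locus z statistics: sign(logFC) * sqrt(LR)."""
    return np.sign(table["logFC"].to_numpy()) * np.sqrt(table["LR"].to_numpy())


def _resolve(ids, index: pd.Index) -> np.ndarray:
    pos = index.get_indexer(pd.Index(ids))
    return pos[pos >= 0]


def rotation_test_from_z(
    z: np.ndarray,
    sets: Sequence[WeightedGeneSet],
    row_ids: Sequence | None = None,
    n_rotations: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rotation gene-set tests given per-locus z statistics.

    For each set, the directional statistic is the weighted mean of z
    (standardized by the weight norm) and the mixed statistic is the mean
    of z squared.  Directional p-values are two-sided tails under random
    rotations; with ``n_rotations=0`` a normal / chi-square approximation
    to the rotation null is used instead.  FDR is Benjamini-Hochberg
    across sets.
    """
    z = np.asarray(z, dtype=float)
    G = len(z)
    index = pd.Index(row_ids) if row_ids is not None else pd.RangeIndex(G)
    rng = np.random.default_rng(seed)
    z_norm2 = float(z @ z)

    rows = []
    for gene_set in sets:
        pos = index.get_indexer(pd.Index(gene_set.ids))
        found = pos >= 0
        idx = pos[found]
        if (~found).any():
            _logger.info("gene set %r: dropped %d unresolvable ids", gene_set.name, int((~found).sum()))
        if len(idx) == 0:
            raise ValueError(f"gene set {gene_set.name!r} resolves to no rows")
        m = len(idx)
        if gene_set.weights is not None:
            w = np.asarray(list(gene_set.weights), dtype=float)[found]
        else:
            w = np.ones(m)
        zs = z[idx]
        wnorm = np.sqrt(float(w @ w))
        stat_dir = float(w @ zs) / wnorm if wnorm > 0 else 0.0
        stat_mixed = float(zs @ zs) / m
        direction = "Up" if (w @ zs if wnorm > 0 else zs.sum()) >= 0 else "Down"

        if n_rotations > 0:
            extreme_dir = 0
            extreme_mixed = 0
            chunk = max(1, int(5e6 / max(m, 1)))
            done = 0
            while done < n_rotations:
                b = min(chunk, n_rotations - done)
                d = rng.standard_normal((b, m))
                q_rest = rng.chisquare(max(G - m, 1), size=b) if G > m else 0.0
                d_norm2 = np.einsum("bm,bm->b", d, d) + q_rest
                scale = np.sqrt(z_norm2 / d_norm2)
                if wnorm > 0:
                    s_rot = scale * (d @ w) / wnorm
                    extreme_dir += int(np.sum(np.abs(s_rot) >= abs(stat_dir) - 1e-12))
                t_rot = (scale**2) * np.einsum("bm,bm->b", d, d) / m
                extreme_mixed += int(np.sum(t_rot >= stat_mixed - 1e-12))
                done += b
            p_dir = (1 + extreme_dir) / (n_rotations + 1) if wnorm > 0 else 1.0
            p_mixed = (1 + extreme_mixed) / (n_rotations + 1)
        else:
            # analytic approximation to the rotation null (large G)
            if wnorm > 0:
                p_dir = 2.0 * stats.norm.sf(abs(stat_dir) * np.sqrt(G / z_norm2))
            else:
                p_dir = 1.0
            p_mixed = stats.chi2.sf(stat_mixed * m * G / z_norm2, df=m)

        rows.append((gene_set.name, m, direction, p_dir, p_mixed))

    result = pd.DataFrame(
        rows, columns=["set", "NGenes", "Direction", "PValue", "PValue_Mixed"]
    ).set_index("set")
    result["FDR"] = benjamini_hochberg(result["PValue"].to_numpy())
    result["FDR_Mixed"] = benjamini_hochberg(result["PValue_Mixed"].to_numpy())
    return result[["NGenes", "Direction", "PValue", "FDR", "PValue_Mixed", "FDR_Mixed"]]


def rotation_gene_set_test(
    fit_obj: NBGLMFit,
    contrast,
    sets: Sequence[WeightedGeneSet],
    n_rotations: int = 9999,
    seed: int | None = None,
    row_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Directional and mixed rotation gene-set tests for a fitted model.

    Runs the per-locus likelihood-ratio test for ``contrast``, converts
    it to signed-root z statistics, and tests each set with
    :func:`rotation_test_from_z`.  Set ids resolve against ``row_ids``
    (default: the fit's gene annotation index, else row numbers).
    """
    result = lrt(fit_obj, contrast)
    z = signed_sqrt_lr(result.table)
    if row_ids is None and fit_obj.genes is not None and "gene_id" in fit_obj.genes.columns:
        gene_ids = fit_obj.genes["gene_id"]
        if gene_ids.is_unique:  # gene-level fits key sets by gene id
            row_ids = gene_ids
    return rotation_test_from_z(z, sets, row_ids=row_ids, n_rotations=n_rotations, seed=seed)


@dataclass
class OriginRegression:
    """Least-squares regression line through the origin."""

    slope: float
    stderr: float
    tvalue: float
    pvalue: float
    n: int


def regression_through_origin(x, y) -> OriginRegression:
    """Least-squares fit of y on x with no intercept.

    Pairs with a missing (NaN) response are dropped.  The slope is
    sum(xy)/sum(x^2) with n - 1 residual degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 finite paired observations")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all x values are zero; slope undefined")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    s2 = float(resid @ resid) / (n - 1)
    stderr = np.sqrt(s2 / sxx)
    if stderr == 0:
        tval, pval = np.inf * np.sign(slope) if slope != 0 else 0.0, 0.0 if slope != 0 else 1.0
    else:
        tval = slope / stderr
        pval = 2.0 * stats.t.sf(abs(tval), df=n - 1)
    return OriginRegression(slope=slope, stderr=float(stderr), tvalue=float(tval), pvalue=float(pval), n=n)


def barcode_data(
    ranking_stat: pd.Series,
    weights: pd.Series,
    n_grid: int = 101,
    bandwidth: float = 0.05,
):
    """Plot-ready data for a barcode enrichment plot.

    Genes are sorted by the ranking statistic (most down-regulated on the
    left).  Weighted genes are split into a positive and a negative
    track; each track's "worm" is a kernel-smoothed density of the
    track's (|weight|-weighted) rank positions relative to the uniform
    expectation, so a flat worm at 1 means no positional enrichment.

    Returns a dict with the sort order, per-track bar positions/heights
    (positions rescaled to [0, 1]) and the worm curves.
    """
    ranking_stat = pd.Series(ranking_stat)
    weights = pd.Series(weights).reindex(ranking_stat.index).fillna(0.0)
    order = np.argsort(ranking_stat.to_numpy(), kind="stable")
    n = len(ranking_stat)
    w_sorted = weights.to_numpy()[order]
    positions = (np.arange(n) + 0.5) / n
    grid = np.linspace(0.0, 1.0, n_grid)

    def worm(track_mask: np.ndarray) -> np.ndarray:
        wts = np.abs(w_sorted[track_mask])
        if wts.sum() == 0:
            return np.ones(n_grid)
        pos = positions[track_mask]
        diff = (grid[:, None] - pos[None, :]) / bandwidth
        kern = np.exp(-0.5 * diff**2)
        # boundary-corrected: each kernel renormalized by its mass in [0,1]
        mass = stats.norm.cdf((1.0 - pos) / bandwidth) - stats.norm.cdf(-pos / bandwidth)
        density = (kern / (bandwidth * np.sqrt(2 * np.pi))) @ (wts / mass)
        return density / wts.sum()

    pos_mask = w_sorted > 0
    neg_mask = w_sorted < 0
    return {
        "order": order,
        "positions": positions,
        "bar_positions_pos": positions[pos_mask],
        "bar_heights_pos": w_sorted[pos_mask],
        "bar_positions_neg": positions[neg_mask],
        "bar_heights_neg": w_sorted[neg_mask],
        "worm_x": grid,
        "worm_pos": worm(pos_mask),
        "worm_neg": worm(neg_mask),
    }
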
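"""Pipeline stages around the GLM core.

Coverage filtering, pair-equalized library sizes, M-values, leading-logFC
multidimensional scaling, promoter-window aggregation of CpG counts, and
lowess profiles of methylation against TSS distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .experiment import MethylationExperiment

__all__ = [
    "coverage_filter",
    "equalize_pair_libsizes",
    "m_values",
    "leading_logfc_mds",
    "PromoterWindow",
    "promoter_aggregate",
    "tss_distance_profile",
]


def coverage_filter(
    exp: MethylationExperiment, min_total: int = 8, min_samples: int | str = "all"
) -> MethylationExperiment:
    """Keep loci with total coverage >= ``min_total`` in enough samples.

    Methylation levels are only meaningfully measurable at loci with
    adequate read depth; the default requires a total (Me + Un) count of
    at least 8 in every sample.  Library sizes are recomputed from the
    retained rows.
    """
    if exp.n_samples < 1:
        raise ValueError("experiment has no samples")
    need = exp.n_samples if min_samples == "all" else int(min_samples)
    enough = (exp.totals() >= min_total).sum(axis=1) >= need
    return exp.subset_rows(enough)


def equalize_pair_libsizes(exp: MethylationExperiment, mode: str = "average") -> MethylationExperiment:
    """Give the Me and Un columns of each sample one shared library size.

    The pair of libraries holding a sample's methylated and unmethylated
    reads must be treated on the same scale, so both columns get the
    average (default) or the sum of the pair's library sizes.  Because
    likelihood-ratio inference is invariant to a common scaling of the
    library sizes, the two modes give identical p-values; logCPM values
    differ by exactly 1.
    """
    if mode not in ("average", "sum"):
        raise ValueError("mode must be 'average' or 'sum'")
    out = exp.copy()
    lib = out.lib_sizes
    pair = lib[0::2] + lib[1::2]
    if mode == "average":
        pair = pair / 2.0
    out.samples["lib_size"] = np.repeat(pair, 2)
    return out


def m_values(exp: MethylationExperiment, prior: float = 2.0) -> pd.DataFrame:
    """Empirical base-2 logit methylation level per locus per sample.

    M = log2(Me + prior) - log2(Un + prior); the prior count avoids
    logarithms of zero.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    M = np.log2(exp.me_counts() + prior) - np.log2(exp.un_counts() + prior)
    return pd.DataFrame(M, columns=exp.sample_names)


def leading_logfc_mds(M, top: int = 500, ndim: int = 2):
    """Classical MDS on leading-logFC distances between samples.

    The distance between two samples is the root-mean-square of the
    ``top`` largest absolute M-value differences between them, i.e. the
    average logit methylation change over the loci most differentially
    methylated for that pair.  Coordinates come from Torgerson double
    centering and an eigendecomposition.

    Returns ``(coordinates, distances)`` as DataFrames.
    """
    M = pd.DataFrame(M)
    names = list(M.columns)
    X = M.to_numpy(dtype=float)
    G, n = X.shape
    if n < 3 and ndim >= 2:
        raise ValueError("at least 3 samples are required for a 2-D MDS solution")
    if top > G:
        warnings.warn(f"top={top} exceeds the {G} available loci; using all loci")
        top = G
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(X[:, i] - X[:, j])
            # ties at the cutoff resolve by locus order (stable partition)
            if top < G:
                order = np.argsort(-diff, kind="stable")[:top]
                sel = diff[order]
            else:
                sel = diff
            D[i, j] = D[j, i] = np.sqrt(np.mean(sel**2))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :ndim] * np.sqrt(np.maximum(vals[:ndim], 0.0))
    coords_df = pd.DataFrame(coords, index=names, columns=[f"dim{d+1}" for d in range(ndim)])
    return coords_df, pd.DataFrame(D, index=names, columns=names)


@dataclass
class PromoterWindow:
    """Promoter window around the TSS, in bp along the direction of
    transcription: ``upstream`` before the TSS, ``downstream`` after it."""

    upstream: int = 2000
    downstream: int = 1000

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")


def promoter_aggregate(
    exp: MethylationExperiment, window: PromoterWindow | None = None
) -> MethylationExperiment:
    """Sum CpG counts within each gene's promoter window.

    The experiment must carry nearest-TSS annotation (``gene_id`` and
    signed ``distance`` columns).  Since positive distances mean the CpG
    lies upstream of the TSS, the window "``upstream`` bp upstream to
    ``downstream`` bp downstream" selects distances in
    ``[-downstream, +upstream]``.  Counts are summed per gene per column;
    gene rows appear in order of first occurrence and library sizes are
    recomputed.
    """
    if window is None:
        window = PromoterWindow()
    for col in ("gene_id", "distance"):
        if col not in exp.loci.columns:
            raise ValueError(f"experiment lacks TSS annotation column {col!r}")
    d = exp.loci["distance"].to_numpy()
    in_window = (d >= -window.downstream) & (d <= window.upstream)
    sub_counts = exp.counts[in_window]
    sub_loci = exp.loci.loc[in_window]

    codes, uniques = pd.factorize(sub_loci["gene_id"], sort=False)
    n_genes = len(uniques)
    counts = np.zeros((n_genes, exp.counts.shape[1]), dtype=exp.counts.dtype)
    np.add.at(counts, codes, sub_counts)

    first = ~sub_loci["gene_id"].duplicated()
    meta_cols = [c for c in ("chrom", "symbol", "strand", "width") if c in sub_loci.columns]
    loci = sub_loci.loc[first, ["gene_id"] + meta_cols].reset_index(drop=True)

    samples = exp.samples.copy()
    samples["lib_size"] = counts.sum(axis=0)
    return MethylationExperiment(counts, loci, samples)


def tss_distance_profile(
    distances, values, max_abs_distance: float, span: float = 0.3
) -> pd.DataFrame:
    """Lowess-smoothed methylation profile against signed TSS distance.

    Restricts to |distance| < ``max_abs_distance`` and applies locally
    weighted scatterplot smoothing (tricube weights, 3 robustness
    iterations) with the given span fraction.  Returns a sorted (x, y)
    curve ready for plotting.
    """
    if max_abs_distance <= 0:
        raise ValueError("max_abs_distance must be positive")
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = (np.abs(d) < max_abs_distance) & np.isfinite(v)
    if keep.sum() < 10:
        raise ValueError(f"only {keep.sum()} points within the window; need at least 10")
    smoothed = sm.nonparametric.lowess(v[keep], d[keep], frac=span, it=3)
    return pd.DataFrame({"distance": smoothed[:, 0], "value": smoothed[:, 1]})
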
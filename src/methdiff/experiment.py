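"""Container for paired methylated/unmethylated count data.

A BS-seq experiment is stored as an integer count matrix with two columns
per DNA sample: the number of reads calling each CpG methylated (``Me``)
and unmethylated (``Un``).  Columns are interleaved sample by sample
(sample1-Me, sample1-Un, sample2-Me, ...), mirroring the layout produced
by collating Bismark coverage files.  Row metadata (chromosome, position
and optional nearest-gene annotation) lives in ``loci``; column metadata
(sample, Me/Un flag, group, library size, normalization factor) lives in
``samples``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationExperiment",
    "make_experiment",
    "write_experiment",
    "read_experiment",
]

SAMPLE_COLUMNS = ["sample", "meth", "group", "lib_size", "norm_factor"]


@dataclass
class MethylationExperiment:
    """Per-locus Me/Un counts plus locus and sample metadata.

    Attributes
    ----------
    counts:
        ``(n_loci, 2 * n_samples)`` non-negative integer matrix, columns
        alternating Me/Un per sample.
    loci:
        One row per count row; at least ``chrom`` and ``pos`` columns
        (1-based positions) for CpG-level data, or ``gene_id`` for
        gene-level data.
    samples:
        One row per count column, indexed by the column label
        (``"<sample>-Me"`` / ``"<sample>-Un"``).
    """

    counts: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape[1] % 2 != 0:
            raise ValueError("counts must have an even number of columns (Me/Un pairs)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.loci) != self.counts.shape[0]:
            raise ValueError("loci must have one row per count row")
        if len(self.samples) != self.counts.shape[1]:
            raise ValueError("samples must have one row per count column")

    # -- basic geometry -------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1] // 2

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples["sample"].iloc[0::2])

    @property
    def group(self) -> pd.Series:
        return self.samples["group"]

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.samples["lib_size"].to_numpy(dtype=float)

    @property
    def norm_factors(self) -> np.ndarray:
        return self.samples["norm_factor"].to_numpy(dtype=float)

    def me_counts(self) -> np.ndarray:
        """Methylated counts, one column per sample."""
        return self.counts[:, 0::2]

    def un_counts(self) -> np.ndarray:
        """Unmethylated counts, one column per sample."""
        return self.counts[:, 1::2]

    def totals(self) -> np.ndarray:
        """Total read coverage (Me + Un) per locus per sample."""
        return self.me_counts() + self.un_counts()

    # -- manipulation ---------------------------------------------------
    def subset_rows(self, rows, recompute_lib_sizes: bool = True) -> "MethylationExperiment":
        """Return a new experiment restricted to the given rows.

        By default library sizes are recomputed as the column sums of the
        retained rows (the equivalent of ``keep.lib.sizes=FALSE``).
        """
        rows = np.asarray(rows)
        idx = np.flatnonzero(rows) if rows.dtype == bool else rows
        counts = self.counts[idx]
        loci = self.loci.iloc[idx].reset_index(drop=True)
        samples = self.samples.copy()
        if recompute_lib_sizes:
            samples["lib_size"] = counts.sum(axis=0)
        return MethylationExperiment(counts, loci, samples)

    def copy(self) -> "MethylationExperiment":
        return MethylationExperiment(self.counts.copy(), self.loci.copy(), self.samples.copy())

    def set_groups(self, groups) -> None:
        """Assign a group label per sample (expanded to both Me/Un columns)."""
        groups = list(groups)
        if len(groups) != self.n_samples:
            raise ValueError(f"expected {self.n_samples} group labels, got {len(groups)}")
        self.samples["group"] = np.repeat(groups, 2)


def make_experiment(
    me: np.ndarray,
    un: np.ndarray,
    sample_names,
    loci: pd.DataFrame | None = None,
    groups=None,
) -> MethylationExperiment:
    """Assemble an experiment from separate Me and Un count matrices."""
    me = np.asarray(me)
    un = np.asarray(un)
    if me.shape != un.shape:
        raise ValueError("me and un matrices must have the same shape")
    n_loci, n_samples = me.shape
    sample_names = list(sample_names)
    if len(sample_names) != n_samples:
        raise ValueError("one sample name per column required")
    counts = np.empty((n_loci, 2 * n_samples), dtype=np.int64)
    counts[:, 0::2] = me
    counts[:, 1::2] = un
    if loci is None:
        loci = pd.DataFrame(index=pd.RangeIndex(n_loci))
    labels = [f"{s}-{m}" for s in sample_names for m in ("Me", "Un")]
    samples = pd.DataFrame(
        {
            "sample": np.repeat(sample_names, 2),
            "meth": ["Me", "Un"] * n_samples,
            "group": np.repeat(list(groups) if groups is not None else [""] * n_samples, 2),
            "lib_size": counts.sum(axis=0),
            "norm_factor": 1.0,
        },
        index=labels,
    )
    return MethylationExperiment(counts, loci.reset_index(drop=True), samples)


def write_experiment(exp: MethylationExperiment, directory: str | os.PathLike) -> None:
    """Serialize an experiment to a directory of TSV files."""
    os.makedirs(directory, exist_ok=True)
    counts = pd.DataFrame(exp.counts, columns=exp.samples.index)
    counts.to_csv(os.path.join(directory, "counts.tsv"), sep="\t", index=False)
    exp.loci.to_csv(os.path.join(directory, "loci.tsv"), sep="\t", index=False)
    exp.samples.to_csv(os.path.join(directory, "samples.tsv"), sep="\t", index=True, index_label="label")


def read_experiment(directory: str | os.PathLike) -> MethylationExperiment:
    """Load an experiment previously written by :func:`write_experiment`."""
    counts = pd.read_csv(os.path.join(directory, "counts.tsv"), sep="\t").to_numpy(dtype=np.int64)
    loci = pd.read_csv(os.path.join(directory, "loci.tsv"), sep="\t")
    samples = pd.read_csv(os.path.join(directory, "samples.tsv"), sep="\t", index_col="label")
    samples["group"] = samples["group"].fillna("")
    return MethylationExperiment(counts, loci, samples)
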
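"""Reading, collating, filtering and annotating Bismark coverage data.

Bismark's ``bismark_methylation_extractor`` emits one coverage file per
sample: tab-delimited, no header, six columns — chromosome, start, end
(equal to start), methylation percentage, methylated count, unmethylated
count — with 1-based inclusive positions.  Only columns 1, 2, 5 and 6
carry information; column 3 duplicates column 2 and column 4 is a
function of columns 5-6.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .experiment import MethylationExperiment

__all__ = [
    "CpGRecord",
    "read_coverage_file",
    "collate",
    "filter_chromosomes",
    "sort_genomic",
    "annotate_nearest_tss",
    "read_tss_table",
    "read_sample_sheet",
    "MOUSE_CHROMOSOMES",
]

#: Default genomic ordering for the mouse genome (autosomes then X).
MOUSE_CHROMOSOMES = [f"chr{i}" for i in range(1, 20)] + ["chrX"]


class CpGRecord(NamedTuple):
    """One CpG locus from a coverage file (1-based position)."""

    chrom: str
    pos: int
    me: int
    un: int


class CoverageFormatError(ValueError):
    """Raised when a coverage file violates the Bismark dialect."""


def _open_text(path):
    with open(path, "rb") as handle:
        magic = handle.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage_file(path: str | os.PathLike) -> list[CpGRecord]:
    """Parse a (possibly gzipped) Bismark coverage file.

    Returns one :class:`CpGRecord` per line using columns 1 (chromosome),
    2 (position), 5 (methylated count) and 6 (unmethylated count).

    Raises
    ------
    CoverageFormatError
        If a line has fewer than six columns or a non-integer position or
        count field; the error message identifies the offending line.
    """
    records: list[CpGRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: expected >=6 tab-separated columns, got {len(fields)}"
                )
            try:
                pos = int(fields[1])
                me = int(fields[4])
                un = int(fields[5])
            except ValueError as err:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: non-integer position or count field ({err})"
                ) from None
            if me < 0 or un < 0 or pos < 1:
                raise CoverageFormatError(
                    f"{path}: line {lineno}: counts must be >=0 and position >=1"
                )
            records.append(CpGRecord(fields[0], pos, me, un))
    return records


def _records_frame(records: Iterable[CpGRecord]) -> pd.DataFrame:
    rec = list(records)
    if not rec:
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
                             "me": pd.Series(dtype=np.int64), "un": pd.Series(dtype=np.int64)})
    return pd.DataFrame(rec, columns=["chrom", "pos", "me", "un"])


def collate(
    per_sample_records: Sequence[Iterable[CpGRecord]],
    sample_names: Sequence[str],
    groups=None,
) -> MethylationExperiment:
    """Collate per-sample CpG records into one experiment.

    Rows are the union of (chrom, pos) keys across samples, in order of
    first appearance; a locus missing from a sample contributes zero
    counts for both its columns.  Library sizes are the column sums.
    """
    sample_names = list(sample_names)
    if len(set(sample_names)) != len(sample_names):
        raise ValueError("sample names must be unique")
    if len(per_sample_records) != len(sample_names):
        raise ValueError("one record list per sample required")

    frames = []
    for name, records in zip(sample_names, per_sample_records):
        frame = _records_frame(records)
        dup = frame.duplicated(["chrom", "pos"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                f"duplicate locus {row['chrom']}:{row['pos']} in sample {name!r}"
            )
        frames.append(frame)

    # union of keys in first-appearance order
    keys = pd.concat(
        [f[["chrom", "pos"]] for f in frames], ignore_index=True
    ).drop_duplicates(ignore_index=True)
    key_index = pd.MultiIndex.from_frame(keys)

    n_loci = len(keys)
    counts = np.zeros((n_loci, 2 * len(sample_names)), dtype=np.int64)
    for j, frame in enumerate(frames):
        if len(frame) == 0:
            continue
        locs = key_index.get_indexer(pd.MultiIndex.from_frame(frame[["chrom", "pos"]]))
        counts[locs, 2 * j] = frame["me"].to_numpy()
        counts[locs, 2 * j + 1] = frame["un"].to_numpy()

    loci = keys.copy()
    labels = [f"{s}-{m}" for s in sample_names for m in ("Me", "Un")]
    samples = pd.DataFrame(
        {
            "sample": np.repeat(sample_names, 2),
            "meth": ["Me", "Un"] * len(sample_names),
            "group": np.repeat(list(groups) if groups is not None else [""] * len(sample_names), 2),
            "lib_size": counts.sum(axis=0),
            "norm_factor": 1.0,
        },
        index=labels,
    )
    return MethylationExperiment(counts, loci, samples)


def filter_chromosomes(
    exp: MethylationExperiment,
    drop_patterns: Sequence[str] = ("random", "chrUn"),
    drop_names: Sequence[str] = ("chrY", "chrM"),
) -> MethylationExperiment:
    """Drop loci on unassembled or unwanted chromosomes.

    A locus is removed when its chromosome name contains any of
    ``drop_patterns`` as a substring, or equals any of ``drop_names``
    exactly.  Library sizes are recomputed from the retained rows.
    """
    chrom = exp.loci["chrom"].astype(str)
    drop = np.zeros(exp.n_loci, dtype=bool)
    for pat in drop_patterns:
        drop |= chrom.str.contains(pat, regex=False).to_numpy()
    for name in drop_names:
        drop |= (chrom == name).to_numpy()
    return exp.subset_rows(~drop)


def sort_genomic(exp: MethylationExperiment, chrom_order: Sequence[str] = MOUSE_CHROMOSOMES) -> MethylationExperiment:
    """Sort loci by chromosome (in the given order) then position; stable."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    chrom = exp.loci["chrom"].astype(str)
    missing = set(chrom.unique()) - set(rank)
    if missing:
        raise ValueError(f"chromosome(s) not in chrom_order: {sorted(missing)}")
    order = np.lexsort((exp.loci["pos"].to_numpy(), chrom.map(rank).to_numpy()))
    return exp.subset_rows(order, recompute_lib_sizes=False)


def read_tss_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a headered TSS annotation TSV.

    Expected columns: ``gene_id``, ``symbol``, ``chrom``, ``strand``
    (+/-), ``tss_pos`` (1-based), ``width`` (gene width in bp).
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "symbol", "chrom", "strand", "tss_pos", "width"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"TSS table missing column(s): {sorted(missing)}")
    return table


def annotate_nearest_tss(exp: MethylationExperiment, tss_table: pd.DataFrame) -> MethylationExperiment:
    """Annotate each locus with the gene whose TSS is nearest.

    The assigned gene minimizes the absolute genomic distance between
    the CpG position and the TSS on the same chromosome, with ties going
    to the gene listed earlier in ``tss_table``.  The reported distance
    is transcription-oriented: ``tss_pos - pos`` for plus-strand genes
    and ``pos - tss_pos`` for minus-strand genes, so a positive value
    always means the TSS lies downstream of the CpG (the CpG is upstream
    of the gene).
    """
    out = exp.copy()
    tss_table = tss_table.reset_index(drop=True)
    chrom = out.loci["chrom"].astype(str).to_numpy()
    pos = out.loci["pos"].to_numpy()

    missing = set(np.unique(chrom)) - set(tss_table["chrom"].astype(str).unique())
    if missing:
        raise ValueError(f"no TSS entries for chromosome(s): {sorted(missing)}")

    assigned = np.full(out.n_loci, -1, dtype=np.int64)
    for chrom_name, sub in tss_table.groupby("chrom", sort=False):
        mask = chrom == str(chrom_name)
        if not mask.any():
            continue
        # sort TSSs by position; for equal positions keep table order so
        # that distance ties resolve to the earlier table entry
        order = np.argsort(sub["tss_pos"].to_numpy(), kind="stable")
        tss_pos = sub["tss_pos"].to_numpy()[order]
        table_idx = sub.index.to_numpy()[order]
        p = pos[mask]
        right = np.searchsorted(tss_pos, p)
        left = np.clip(right - 1, 0, len(tss_pos) - 1)
        right = np.clip(right, 0, len(tss_pos) - 1)
        dist_left = np.abs(p - tss_pos[left])
        dist_right = np.abs(p - tss_pos[right])
        pick_left = dist_left < dist_right
        tie = dist_left == dist_right
        # equidistant: earlier table row wins
        pick_left |= tie & (table_idx[left] < table_idx[right])
        choice = np.where(pick_left, left, right)
        assigned[mask] = table_idx[choice]

    genes = tss_table.iloc[assigned].reset_index(drop=True)
    strand = genes["strand"].to_numpy()
    tsspos = genes["tss_pos"].to_numpy()
    distance = np.where(strand == "-", pos - tsspos, tsspos - pos)
    out.loci["gene_id"] = genes["gene_id"].to_numpy()
    out.loci["symbol"] = genes["symbol"].to_numpy()
    out.loci["strand"] = strand
    out.loci["distance"] = distance.astype(np.int64)
    out.loci["width"] = genes["width"].to_numpy()
    return out


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV with columns ``sample``, ``group``, ``file``."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group", "file"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    return sheet
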
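"""Synthetic BS-seq experiments and Bismark-format fixtures.

The generator emulates the count model used throughout the package: at
locus g in sample i of condition c, the methylated and unmethylated
counts are independent negative-binomial draws

    me ~ NB(mean = c_gi * p_gc,       dispersion = phi)
    un ~ NB(mean = c_gi * (1 - p_gc), dispersion = phi)

sharing one dispersion, where p_gc is the logistic transform (base 2) of
the condition's logit methylation level and c_gi is the expected
coverage.  Coverage is heterogeneous across samples: each sample gets a
log-normal scale factor multiplying the global mean coverage, mimicking
the unequal library sizes of real RRBS samples.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ObservationDesign, design_from_groups, make_contrast
from .experiment import MethylationExperiment, make_experiment

__all__ = [
    "SimulationSpec",
    "simulate_experiment",
    "write_bismark_coverage",
    "ToyExample",
    "toy_fixtures",
]


@dataclass
class SimulationSpec:
    """Stated world for a simulated two-or-more-group RRBS experiment.

    Parameters
    ----------
    n_loci:
        Number of CpG loci.
    groups / replicates:
        Condition names and replicates per condition.
    baseline_logit_sd:
        Per-locus baseline methylation levels are drawn N(0, sd) on the
        base-2 logit scale (logit 0 = 50% methylated); a float or array
        ``baseline_logit`` overrides the draw.
    effect_fraction / effect_size / effect_direction:
        Fraction of loci receiving a shift of ``effect_size`` base-2
        logit units in the second group; ``effect_direction`` is
        ``"both"`` (alternating sign, the default), ``"up"`` or
        ``"down"``.
    coverage_mean / coverage_sample_sigma:
        Expected per-locus read coverage, and the sigma of the
        log-normal per-sample scale factors modeling unequal sequencing
        depth.
    dispersion:
        Shared NB dispersion phi (variance mu + phi mu^2); the default
        is the magnitude typical of replicated RRBS data.
    chrom_lengths:
        Loci positions are drawn along these chromosomes in order.
    """

    n_loci: int = 1000
    groups: tuple = ("A", "B")
    replicates: tuple = (3, 3)
    baseline_logit: float | np.ndarray | None = None
    baseline_logit_sd: float = 1.5
    effect_fraction: float = 0.1
    effect_size: float = 2.0
    effect_direction: str = "both"
    coverage_mean: float = 30.0
    coverage_sample_sigma: float = 0.3
    dispersion: float = 0.0275
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 50_000_000})
    seed: int | None = None

    def validate(self) -> None:
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if len(self.groups) != len(self.replicates):
            raise ValueError("groups and replicates must have equal length")
        if any(r < 1 for r in self.replicates):
            raise ValueError("replicates must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.effect_direction not in ("both", "up", "down"):
            raise ValueError("effect_direction must be 'both', 'up' or 'down'")
        if self.effect_fraction > 0 and len(self.groups) < 2:
            raise ValueError("effects require at least two groups")


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def _positions(rng: np.random.Generator, n: int, chrom_lengths: dict) -> pd.DataFrame:
    chroms = list(chrom_lengths)
    per = np.full(len(chroms), n // len(chroms))
    per[: n % len(chroms)] += 1
    rows_chrom, rows_pos = [], []
    for chrom, m in zip(chroms, per):
        if m == 0:
            continue
        gap_high = max(2, int(2 * chrom_lengths[chrom] / max(m, 1)))
        gaps = rng.integers(1, gap_high, size=m)
        pos = np.cumsum(gaps)
        rows_chrom.extend([chrom] * m)
        rows_pos.append(pos)
    return pd.DataFrame(
        {"chrom": rows_chrom, "pos": np.concatenate(rows_pos) if rows_pos else np.array([], dtype=np.int64)}
    )


def simulate_experiment(spec: SimulationSpec) -> tuple[MethylationExperiment, pd.DataFrame]:
    """Simulate an experiment; returns (experiment, truth table).

    The truth table holds the true methylation proportion per group, the
    true base-2 logit difference of the last group versus the first
    (``true_logFC``) and an ``is_effect`` flag per locus.  Identical
    seeds reproduce identical experiments.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G = spec.n_loci
    n_groups = len(spec.groups)

    if spec.baseline_logit is None:
        base = rng.normal(0.0, spec.baseline_logit_sd, size=G)
    else:
        base = np.broadcast_to(np.asarray(spec.baseline_logit, dtype=float), (G,)).copy()

    logits = np.tile(base[:, None], (1, n_groups))
    is_effect = np.zeros(G, dtype=bool)
    if spec.effect_fraction > 0 and G > 0:
        n_eff = int(round(spec.effect_fraction * G))
        eff_idx = rng.choice(G, size=n_eff, replace=False)
        if spec.effect_direction == "both":
            signs = np.where(np.arange(n_eff) % 2 == 0, 1.0, -1.0)
        else:
            signs = np.full(n_eff, 1.0 if spec.effect_direction == "up" else -1.0)
        logits[eff_idx, 1] += signs * spec.effect_size
        is_effect[eff_idx] = True

    p = 1.0 / (1.0 + 2.0 ** (-logits))  # base-2 logistic

    sample_names, group_of_sample = [], []
    for g, r in zip(spec.groups, spec.replicates):
        for j in range(r):
            sample_names.append(f"{g}_{j+1}")
            group_of_sample.append(g)
    n = len(sample_names)
    scale = np.exp(rng.normal(0.0, spec.coverage_sample_sigma, size=n))
    coverage = spec.coverage_mean * scale  # per-sample expected coverage

    me = np.zeros((G, n), dtype=np.int64)
    un = np.zeros((G, n), dtype=np.int64)
    group_index = {g: i for i, g in enumerate(spec.groups)}
    for i, g in enumerate(group_of_sample):
        pc = p[:, group_index[g]]
        me[:, i] = _nb_draws(rng, coverage[i] * pc, spec.dispersion)
        un[:, i] = _nb_draws(rng, coverage[i] * (1.0 - pc), spec.dispersion)

    loci = _positions(rng, G, spec.chrom_lengths)
    exp = make_experiment(me, un, sample_names, loci=loci, groups=group_of_sample)

    truth = pd.DataFrame({f"p_{g}": p[:, j] for j, g in enumerate(spec.groups)})
    truth["true_logFC"] = logits[:, -1] - logits[:, 0]
    truth["is_effect"] = is_effect
    return exp, truth


def write_bismark_coverage(
    exp: MethylationExperiment, directory: str | os.PathLike, gzip_output: bool = True
) -> list[str]:
    """Write one Bismark-style coverage file per sample.

    Loci with zero total coverage in a sample are omitted from that
    sample's file (Bismark only reports covered positions).  Column 4 is
    the methylation percentage 100 * me / (me + un).
    """
    os.makedirs(directory, exist_ok=True)
    me = exp.me_counts()
    un = exp.un_counts()
    chrom = exp.loci["chrom"].astype(str).to_numpy()
    pos = exp.loci["pos"].to_numpy()
    paths = []
    for j, name in enumerate(exp.sample_names):
        suffix = ".bismark.cov.gz" if gzip_output else ".bismark.cov"
        path = os.path.join(directory, f"{name}{suffix}")
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as handle:
            for g in range(exp.n_loci):
                total = me[g, j] + un[g, j]
                if total == 0:
                    continue
                pct = 100.0 * me[g, j] / total
                handle.write(f"{chrom[g]}\t{pos[g]}\t{pos[g]}\t{pct:.10g}\t{me[g, j]}\t{un[g, j]}\n")
        paths.append(path)
    return paths


@dataclass
class ToyExample:
    """A desk-scale worked example: counts, design, contrast, dispersion."""

    counts: np.ndarray
    design: ObservationDesign
    lib_sizes: np.ndarray
    dispersion: float
    contrast: np.ndarray
    column_labels: list[str]


def toy_fixtures() -> dict[str, ToyExample]:
    """The two textbook examples used throughout the documentation.

    ``"single"``: one sample per condition, counts (Me, Un) = (2, 12)
    for A and (11, 0) for B.  ``"replicated"``: two replicates per
    condition with the A2 = (4, 20) and B2 = (15, 3) pairs added.  Both
    use library sizes of 100 and a preset dispersion of 0.0247, and test
    condition B versus A.
    """
    single_design = design_from_groups(["A", "B"])
    single = ToyExample(
        counts=np.array([[2, 12, 11, 0]]),
        design=single_design,
        lib_sizes=np.full(4, 100.0),
        dispersion=0.0247,
        contrast=make_contrast(single_design, "ConditionB - ConditionA"),
        column_labels=["A.Me", "A.Un", "B.Me", "B.Un"],
    )
    repl_design = design_from_groups(["A", "A", "B", "B"])
    replicated = ToyExample(
        counts=np.array([[2, 12, 4, 20, 11, 0, 15, 3]]),
        design=repl_design,
        lib_sizes=np.full(8, 100.0),
        dispersion=0.0247,
        contrast=make_contrast(repl_design, "ConditionB - ConditionA"),
        column_labels=["A1.Me", "A1.Un", "A2.Me", "A2.Un", "B1.Me", "B1.Un", "B2.Me", "B2.Un"],
    )
    return {"single": single, "replicated": replicated}
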
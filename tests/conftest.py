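import numpy as np
import pandas as pd
import pytest

import methdiff as md


@pytest.fixture(scope="session")
def toys():
    """The two desk-scale worked examples (single and replicated)."""
    return md.toy_fixtures()


@pytest.fixture()
def tss_table():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "symbol": ["GeneA", "GeneB", "GeneC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+"],
            "tss_pos": [10_000, 50_000, 20_000],
            "width": [5_000, 12_000, 8_000],
        }
    )


@pytest.fixture()
def small_experiment():
    """Deterministic 8-locus, 2-sample experiment across two chromosomes."""
    loci = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5 + ["chr2"] * 3,
            "pos": [9_500, 10_020, 11_500, 49_000, 52_000, 19_100, 20_000, 21_000],
        }
    )
    rng = np.random.default_rng(11)
    me = rng.integers(0, 20, size=(8, 2))
    un = rng.integers(0, 20, size=(8, 2))
    return md.make_experiment(me, un, ["s1", "s2"], loci=loci, groups=["A", "B"])


def simulate(seed=0, **kwargs):
    defaults = dict(n_loci=500, groups=("A", "B"), replicates=(3, 3),
                    coverage_mean=30.0, dispersion=0.0275, seed=seed)
    defaults.update(kwargs)
    return md.simulate_experiment(md.SimulationSpec(**defaults))


@pytest.fixture()
def simulated():
    return simulate(seed=123)
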
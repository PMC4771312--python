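import numpy as np
import pandas as pd
import pytest

from metaltrait import simulate
from metaltrait._trees import TreeArrays


@pytest.fixture(scope="session")
def balanced4():
    """Balanced 4-tip tree with unit branches: ((A:1,B:1):1,(C:1,D:1):1)."""
    return TreeArrays.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule64():
    """64-tip Yule tree shared across statistics tests."""
    return simulate.gen_tree(simulate.SimTreeSpec(64, seed=11))


@pytest.fixture(scope="session")
def yule64_arrays(yule64):
    return TreeArrays(yule64)


def trait(labels, values):
    return pd.Series(list(values), index=list(labels)).astype(int)


@pytest.fixture(scope="session")
def small_genes():
    """Deterministic 3-genome gene table with one planted heme locus."""
    genes, upstreams, planted = simulate.gen_genomes(
        simulate.GenomeSimSpec(
            n_genomes=3,
            genes_per_genome=30,
            locus_templates=[("heme", ("TBDT", "hutB", "hmuS"), 1.0)],
            motif_plant=("AAACCCTGAGGGTTT", 120, 0),
            seed=42,
        )
    )
    return genes, upstreams, planted
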
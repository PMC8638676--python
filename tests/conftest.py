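import numpy as np
import pandas as pd
import pytest

from ribostruct.annotation import IsoformModel, UnionGeneModel, union_isoforms
from ribostruct.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated study shared by read-only unit tests."""
    return simulate_dataset(SimulationConfig(n_genes=300, seed=11))


@pytest.fixture
def single_exon_model():
    return UnionGeneModel(
        gene_id="gA", reference="chr1", strand="+",
        exon_union=((0, 300),), cds_union=((100, 200),),
    )


@pytest.fixture
def two_exon_minus_model():
    return UnionGeneModel(
        gene_id="gB", reference="chr1", strand="-",
        exon_union=((0, 50), (100, 150)), cds_union=((20, 50), (100, 130)),
    )


@pytest.fixture
def multi_isoform_gene():
    isoforms = [
        IsoformModel("gC", "gC.1", "chr2", "+", ((0, 100),), cds=(30, 90)),
        IsoformModel("gC", "gC.2", "chr2", "+", ((50, 150),), cds=(60, 120)),
    ]
    return union_isoforms(isoforms)["gC"]


def make_footprints(rows):
    """rows: (reference, five_prime, length[, strand[, sample]])"""
    full = []
    for r in rows:
        r = tuple(r)
        full.append(r + ("+",) * (4 - len(r)) + ("s1",) * (5 - max(len(r), 4)))
    return pd.DataFrame(full, columns=["reference", "five_prime", "length", "strand", "sample_id"])


@pytest.fixture
def footprint_builder():
    return make_footprints
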
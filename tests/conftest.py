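import numpy as np
import pytest

from somasel.site_counting import FunctionalityTable, GeneModel, Scheme
from somasel.synthetic_data import SimConfig, generate_gene_models


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimConfig(
        n_genes=30,
        cds_length_range=(60, 240),
        n_patients=40,
        mutation_rate=300.0,
        n_germline_sites=800,
        seed=99,
    )


@pytest.fixture
def small_models(small_config):
    return generate_gene_models(small_config)


def make_sift_table(entries: dict) -> FunctionalityTable:
    """entries: {(gene, pos, alt_aa): score}"""
    table = FunctionalityTable(scheme=Scheme.SIFT)
    for key, score in entries.items():
        table.add(*key, score)
    return table


def make_pph_table(entries: dict) -> FunctionalityTable:
    table = FunctionalityTable(scheme=Scheme.POLYPHEN)
    for key, cls in entries.items():
        table.add(*key, cls)
    return table


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free CDS, independent of the package generators."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)


@pytest.fixture
def simple_gene():
    return GeneModel("g1", "t1", "ATGTTTTGG")
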
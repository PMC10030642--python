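import numpy as np
import pandas as pd
import pytest

from coevo.types import ExpressionMatrix, Gene, GeneCatalog, MutationRecord, MutationTable


@pytest.fixture
def toy_catalog() -> GeneCatalog:
    """Ten equal 100-bp genes tiling a 1000-bp genome."""
    genes = [
        Gene(f"g{i}", "chr1", i * 100 + 1, (i + 1) * 100) for i in range(10)
    ]
    return GeneCatalog("toy", 1000, genes)


@pytest.fixture
def overlap_catalog() -> GeneCatalog:
    """Two overlapping genes plus one isolated gene."""
    return GeneCatalog(
        "toy", 500,
        [Gene("A", "chr1", 10, 100), Gene("B", "chr1", 80, 160),
         Gene("C", "chr1", 300, 400)],
    )


def make_record(pop="pop_1", pos=50, alt="T", freq=0.5, genes=(),
                contig="chr1", ref="A", mclass="substitution"):
    return MutationRecord(
        population_id=pop, contig=contig, position=pos, ref_allele=ref,
        alt_allele=alt, frequency=freq, mutation_class=mclass,
        gene_ids=tuple(genes),
    )


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes over 2 taxa, 4 samples, hand-written counts."""
    samples = ["s1", "s2", "s3", "s4"]
    counts = pd.DataFrame(
        [[10, 20, 30, 40], [5, 10, 15, 20], [100, 100, 100, 100]],
        index=["tA:g1", "tA:g2", "tB:g1"], columns=samples,
    )
    gene_taxon = pd.Series(
        {"tA:g1": "tA", "tA:g2": "tA", "tB:g1": "tB"}, name="taxon_id"
    )
    meta = pd.DataFrame(
        {"predation": [False, False, True, True],
         "coevolved_prey": [False, True, False, True],
         "day": [4, 4, 4, 4], "replicate": [1, 2, 1, 2]},
        index=samples,
    )
    relabund = pd.DataFrame(
        [[0.6, 0.5, 0.4, 0.5], [0.4, 0.5, 0.6, 0.5]],
        index=["tA", "tB"], columns=samples,
    )
    return ExpressionMatrix(counts, gene_taxon, meta, relabund)
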
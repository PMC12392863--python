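import numpy as np
import pytest

from fapkit.operon import GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


def make_gene(gene_id, start, end, contig="c1", genome="G1", aa=100):
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome,
        contig_id=contig,
        start_bp=start,
        end_bp=end,
        strand="+",
        protein_length_aa=aa,
    )
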
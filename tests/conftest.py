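import pytest

from phageadapt.io import GenomeSequence, GeneRecord


@pytest.fixture
def toy_genome() -> GenomeSequence:
    # 40 bp, mixed composition, no N
    return GenomeSequence(id="toy", residues="ACGTACGGTTCAGGCCAATTGGCCAACTGATCGATCGGAT")


def make_genes(n: int, prefix: str = "G", gene_len: int = 300) -> list[GeneRecord]:
    """n genes laid end to end, 1-based coordinates, aa_length from length."""
    genes = []
    pos = 1
    for i in range(1, n + 1):
        genes.append(
            GeneRecord(
                gene_id=f"{prefix}{i:04d}",
                start=pos,
                end=pos + gene_len - 1,
                strand="+",
                product="p",
                aa_length=gene_len // 3 - 1,
            )
        )
        pos += gene_len
    return genes
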
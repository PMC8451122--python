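"""Rule-based synteny-block calling between two annotated genomes.

A gene in genome A is *syntenic* when it has a homologous partner in
genome B (best hit after alignment-length and e-value filtering). A
synteny block is a maximal chain, in A's gene order, of at least
``min_run`` syntenic genes in which consecutive syntenic genes are
separated by at most ``max_gap`` non-syntenic genes. This operational
rule — minimum five consecutive syntenic genes, at most four intervening
non-syntenic genes, by default — makes no claim about gene-order
conservation on the B side; a strict-colinear mode additionally requires
partner indices in B to increase along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phageadapt.io import GeneRecord, HitRecord, ValidationError


@dataclass
class HomologyPairing:
    """Best-hit pairs (A-gene, B-gene) surviving the homology filter."""

    pairs: set[tuple[str, str]]
    min_aln_bp: int = 10
    max_evalue: float = 1e-5

    @property
    def a_partnered(self) -> set[str]:
        return {a for a, _ in self.pairs}

    def partner_of(self, gene_id_a: str) -> str | None:
        for a, b in self.pairs:
            if a == gene_id_a:
                return b
        return None


@dataclass(frozen=True)
class SyntenyBlock:
    """A called block: index ranges over each genome's gene order (1-based)."""

    a_range: tuple[int, int]
    b_range: tuple[int, int]
    n_syntenic: int
    max_internal_gap: int
    a_gene_ids: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.n_syntenic < 1:
            raise ValidationError("block must contain at least one syntenic gene")


def pair_homologs(
    hits: list[HitRecord],
    genes_a: list[GeneRecord],
    genes_b: list[GeneRecord],
    min_aln_bp: int = 10,
    max_evalue: float = 1e-5,
) -> HomologyPairing:
    """Pair each A-gene with its best B-gene under the homology filter.

    Hits must reference gene ids exactly (queries in A, subjects in B);
    hits shorter than ``min_aln_bp`` or weaker than ``max_evalue`` are
    dropped, then each A-gene keeps its best subject by bitscore (ties:
    lower e-value, then lexicographically smallest subject id).
    """
    ids_a = {g.gene_id for g in genes_a}
    ids_b = {g.gene_id for g in genes_b}
    bad = sorted(
        {h.query_id for h in hits if h.query_id not in ids_a}
        | {h.subject_id for h in hits if h.subject_id not in ids_b}
    )
    if bad:
        raise ValidationError(f"hit ids not found in gene tables: {bad}")
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.aln_length < min_aln_bp or h.evalue > max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query_id] = h
    pairs = {(a, h.subject_id) for a, h in best.items()}
    return HomologyPairing(pairs=pairs, min_aln_bp=min_aln_bp, max_evalue=max_evalue)


def _hit_key(h: HitRecord) -> tuple:
    # best = max bitscore, then min evalue, then lexicographic subject id
    return (-h.bitscore, h.evalue, h.subject_id)


def call_blocks(
    genes_a: list[GeneRecord],
    genes_b: list[GeneRecord],
    pairing: HomologyPairing,
    min_run: int = 5,
    max_gap: int = 4,
    colinear: bool = False,
) -> list[SyntenyBlock]:
    """Call synteny blocks scanning genome A's gene order.

    A block is a maximal chain of syntenic genes in which each pair of
    consecutive syntenic genes is separated by at most ``max_gap``
    non-syntenic A-genes, containing at least ``min_run`` syntenic genes.
    Reported ranges span the first to last syntenic gene of the chain
    (flanking gaps excluded). With ``colinear=True`` the chain additionally
    breaks whenever the B-partner index does not increase.
    """
    partner: dict[str, str] = {}
    for a, b in sorted(pairing.pairs):
        partner[a] = b
    b_index = {g.gene_id: i + 1 for i, g in enumerate(genes_b)}

    chains: list[list[int]] = []  # 0-based A indices of syntenic genes
    current: list[int] = []
    last_b: int | None = None
    for i, g in enumerate(genes_a):
        b = partner.get(g.gene_id)
        if b is None:
            continue
        bi = b_index[b]
        gap_ok = bool(current) and (i - current[-1] - 1) <= max_gap
        colinear_ok = (not colinear) or last_b is None or bi > last_b
        if current and gap_ok and colinear_ok:
            current.append(i)
        else:
            if current:
                chains.append(current)
            current = [i]
        last_b = bi
    if current:
        chains.append(current)

    blocks = []
    for chain in chains:
        if len(chain) < min_run:
            continue
        gaps = [j - i - 1 for i, j in zip(chain, chain[1:])]
        b_indices = [b_index[partner[genes_a[i].gene_id]] for i in chain]
        blocks.append(
            SyntenyBlock(
                a_range=(chain[0] + 1, chain[-1] + 1),
                b_range=(min(b_indices), max(b_indices)),
                n_syntenic=len(chain),
                max_internal_gap=max(gaps) if gaps else 0,
                a_gene_ids=tuple(genes_a[i].gene_id for i in chain),
            )
        )
    return blocks
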
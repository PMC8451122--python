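"""Reciprocal-best-hit read recruitment and abundance normalization.

A phage's environmental distribution is estimated by recruiting reads
from virome sequencing datasets to its predicted ORFs. Two opposite
homology searches are consumed as tabular hit files: a *forward* search
(ORF proteins against the read library) and a *reverse* search (candidate
reads back against the ORF proteins). A read is assigned to an ORF only
when the pairing is a reciprocal best hit — the ORF is the read's best
reverse hit AND the read's best forward hit — which guards against
false-positive homology.

Per-ORF abundance is doubly normalized: recruited reads divided by the
total number of reads in the virome and by the ORF's amino-acid length,
giving the "reads per amino-acid pair" statistic. ORF coverage is the
fraction of ORFs recruiting at least one read.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from phageadapt.io import GeneRecord, HitRecord, ValidationError


@dataclass
class RecruitmentTable:
    """Per-ORF recruitment counts and normalized abundances.

    ``per_orf`` has one row per ORF (columns: orf_id, aa_length,
    n_reads_recruited, abundance) in gene-table order; the scalar totals
    summarize the virome-level result.
    """

    per_orf: pd.DataFrame
    virome_id: str
    total_virome_reads: int
    total_recruited: int
    orf_coverage: float
    pooled_abundance: float


def _best(hits: list[HitRecord], partner: str) -> str | None:
    """Id of the best-scoring partner: max bitscore, min evalue, lex id."""
    if not hits:
        return None
    key = lambda h: (-h.bitscore, h.evalue, getattr(h, partner))
    return getattr(min(hits, key=key), partner)


def rbb_filter(
    forward: list[HitRecord], reverse: list[HitRecord]
) -> set[tuple[str, str]]:
    """Retain (read_id, orf_id) pairs that are reciprocal best hits.

    ``forward`` rows have ORFs as queries and reads as subjects; ``reverse``
    rows have reads as queries and ORFs as subjects. A pair (r, o) survives
    iff o is r's best reverse hit and o is the best forward query among all
    forward rows whose subject is r. "Best" means maximal bitscore, ties
    broken by minimal e-value and then lexicographically smallest id. Each
    read ends up in at most one retained pair.
    """
    fwd_by_read: dict[str, list[HitRecord]] = {}
    for h in forward:
        fwd_by_read.setdefault(h.subject_id, []).append(h)
    rev_by_read: dict[str, list[HitRecord]] = {}
    for h in reverse:
        rev_by_read.setdefault(h.query_id, []).append(h)

    retained = set()
    for read_id, rev_hits in rev_by_read.items():
        best_rev = _best(rev_hits, "subject_id")
        best_fwd = _best(fwd_by_read.get(read_id, []), "query_id")
        if best_fwd is not None and best_rev == best_fwd:
            retained.add((read_id, best_rev))
    return retained


def normalize_abundance(
    n_reads: int, total_virome_reads: int, aa_length: int
) -> float:
    """Reads per amino-acid pair: n / (total virome reads x ORF aa length)."""
    if total_virome_reads <= 0:
        raise ValueError("total_virome_reads must be > 0")
    if aa_length <= 0:
        raise ValueError("aa_length must be > 0")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    return n_reads / (total_virome_reads * aa_length)


def recruitment_report(
    pairs: set[tuple[str, str]],
    orfs: list[GeneRecord],
    total_virome_reads: int,
    virome_id: str = "",
) -> RecruitmentTable:
    """Aggregate retained pairs into the per-ORF recruitment table.

    ``pooled_abundance`` divides the total recruited reads by total virome
    reads and the summed amino-acid length of the ORFs that recruited at
    least one read (0 when nothing recruited).
    """
    if total_virome_reads <= 0:
        raise ValueError("total_virome_reads must be > 0")
    orf_ids = {o.gene_id for o in orfs}
    unknown = sorted({o for _, o in pairs} - orf_ids)
    if unknown:
        raise ValidationError(f"pairs reference unknown ORF ids: {unknown}")

    counts: dict[str, int] = {o.gene_id: 0 for o in orfs}
    for _read, orf in pairs:
        counts[orf] += 1

    rows = []
    for o in orfs:
        n = counts[o.gene_id]
        rows.append(
            {
                "orf_id": o.gene_id,
                "aa_length": o.aa_length,
                "n_reads_recruited": n,
                "abundance": normalize_abundance(n, total_virome_reads, o.aa_length),
            }
        )
    per_orf = pd.DataFrame(rows, columns=["orf_id", "aa_length", "n_reads_recruited", "abundance"])
    total_recruited = int(per_orf["n_reads_recruited"].sum())
    covered = per_orf["n_reads_recruited"] >= 1
    orf_coverage = float(covered.sum() / len(orfs)) if orfs else 0.0
    aa_pool = int(per_orf.loc[covered, "aa_length"].sum())
    pooled = (
        total_recruited / (total_virome_reads * aa_pool) if aa_pool > 0 else 0.0
    )
    return RecruitmentTable(
        per_orf=per_orf,
        virome_id=virome_id,
        total_virome_reads=total_virome_reads,
        total_recruited=total_recruited,
        orf_coverage=orf_coverage,
        pooled_abundance=pooled,
    )
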
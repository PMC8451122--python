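"""Sequence, annotation and homology-table I/O.

File conventions
----------------
* FASTA: multi-record, ids truncated at the first whitespace (the full
  header is kept as ``description``); residues are uppercased on ingest and
  restricted to the ``{A, C, G, T, N}`` alphabet.
* Gene tables: TSV with header ``gene_id start end strand product
  aa_length``; coordinates are 1-based inclusive (GenBank convention);
  ``#``-prefixed lines are comments.
* Homology hits: the standard 12-column BLAST tabular layout
  (``-outfmt 6``): qseqid sseqid pident length mismatch gapopen qstart qend
  sstart send evalue bitscore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGTN")
VALID_STRANDS = frozenset("+-")

#: 12 columns of the tabular BLAST dialect, in order.
HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)

GENE_COLUMNS = ("gene_id", "start", "end", "strand", "product", "aa_length")


class ParseError(ValueError):
    """A file could not be parsed (malformed record, bad alphabet...)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence with declared topology.

    ``residues`` is uppercase over ``{A, C, G, T, N}``; construction rejects
    anything else, so downstream code never re-validates the alphabet.
    """

    id: str
    residues: str
    topology: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: residues must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValidationError(
                f"sequence {self.id!r}: topology must be 'linear' or 'circular', "
                f"got {self.topology!r}"
            )
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues, start=1) if c not in VALID_RESIDUES
            )
            raise ParseError(
                f"sequence {self.id!r}: illegal residue {self.residues[pos - 1]!r} "
                f"at position {pos} (alphabet is A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """A gene model: 1-based inclusive coordinates, strand and product.

    ``aa_length`` is the annotated protein length; when it is derived from
    coordinates the caller should use ``(end - start + 1) // 3 - 1`` (stop
    codon excluded), but an explicitly annotated value always wins.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    aa_length: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.aa_length <= 0:
            raise ValidationError(f"gene {self.gene_id!r}: aa_length must be > 0")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology search."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: pct_identity "
                f"{self.pct_identity} outside [0, 100]"
            )
        if self.aln_length < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative aln_length"
            )
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative evalue"
            )
        if self.bitscore < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative bitscore"
            )


def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeSequence]:
    """Read a multi-record FASTA file into :class:`GenomeSequence` objects.

    Record order is preserved; ids truncate at the first whitespace and the
    full header line is retained as ``description``. Soft-masked (lowercase)
    residues are uppercased and treated as normal.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        out.append(
            GenomeSequence(
                id=rec.id,
                residues=str(rec.seq).upper(),
                topology=topology,
                description=rec.description,
            )
        )
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path) -> None:
    """Write sequences as FASTA with canonical 60-column wrapping."""
    records = [
        SeqRecord(Seq(g.residues), id=g.id, description=g.description or "")
        for g in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def seq_stats(g: GenomeSequence) -> dict:
    """Length, GC fraction and N count of a sequence.

    GC fraction is (G+C)/(A+C+G+T): ambiguous Ns are excluded from the
    denominator. An all-N sequence has undefined GC, reported as ``None``
    rather than 0 so callers cannot mistake it for an AT-rich genome.
    """
    counts = {b: g.residues.count(b) for b in "ACGTN"}
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    gc = (counts["G"] + counts["C"]) / denom if denom else None
    return {"length": len(g), "gc_fraction": gc, "n_count": counts["N"]}


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene table, returning records sorted by start coordinate.

    The header must name the six canonical columns (any order); lines
    starting with ``#`` are skipped. Duplicate gene ids are rejected.
    """
    path = Path(path)
    header: list[str] | None = None
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = set(GENE_COLUMNS) - set(header)
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: gene table header missing columns "
                        f"{sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                rec = GeneRecord(
                    gene_id=row["gene_id"].strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"].strip(),
                    product=row["product"].strip(),
                    aa_length=int(row["aa_length"]),
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if rec.gene_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene_id {rec.gene_id!r}"
                )
            seen.add(rec.gene_id)
            records.append(rec)
    if header is None:
        raise ParseError(f"{path}: empty gene table (no header)")
    records.sort(key=lambda r: (r.start, r.end, r.gene_id))
    return records


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}\t{g.aa_length}\n"
            )


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular homology search result.

    No filtering happens at parse time; an empty file is a valid empty
    search result. Malformed rows are reported with their line number.
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bitscore,
                    )
                )
                + "\n"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return str(Seq(seq).reverse_complement())


def derived_aa_length(start: int, end: int) -> int:
    """Protein length implied by CDS coordinates (stop codon excluded)."""
    return (end - start + 1) // 3 - 1
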
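"""Seeded synthetic inputs with ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis assumes
and returns the planted truth alongside the data, so recovery can be
scored without downloads:

* :func:`make_mosaic_genome` — a background genome sampled from a 3rd-order
  nucleotide Markov chain with a compositionally divergent insert sampled
  from a second chain: the target of tetranucleotide anomaly detection.
  Order-3 chains control 4-mer usage directly, which is exactly the
  signature the profiler reads.
* :func:`make_replichore_genome` — i.i.d. bases with opposite G/C excess on
  the two replichores around a planted origin: the target of cumulative
  GC-skew origin calling.
* :func:`make_synteny_pair` — paired gene tables plus a hit table realizing
  exactly a planted pattern of syntenic runs and gaps.
* :func:`make_recruitment_tables` — forward/reverse hit tables realizing
  Poisson per-ORF read recruitment, with optional decoy reads (forward hit
  only, reciprocity unverifiable) and reciprocity noise (reverse best hit
  reassigned).

All generators are bit-reproducible under a fixed seed. Hit tables are
simulated at the alignment-summary level; no read-level sequence or
quality simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phageadapt.io import GenomeSequence, GeneRecord, HitRecord, ValidationError
from phageadapt.tetra import count_tetra

BASES = "ACGT"


# ---------------------------------------------------------------------------
# order-3 Markov chain machinery


def random_order3_model(rng: np.random.Generator, concentration: float = 20.0) -> np.ndarray:
    """Random 3rd-order transition matrix, shape (64, 4).

    Row k gives P(next base | previous trinucleotide k), trinucleotides in
    lexicographic order. Rows are Dirichlet(concentration) draws: larger
    concentration keeps the chain closer to uniform composition.
    """
    return rng.dirichlet([concentration] * 4, size=64)


def perturb_order3_model(
    model: np.ndarray,
    rng: np.random.Generator,
    strength: float = 1.0,
    concentration: float = 2.0,
) -> np.ndarray:
    """Mix a model with an independent random model to shift its signature.

    ``strength`` in (0, 1] is the mixing weight of the new random component,
    drawn at the given Dirichlet concentration. The defaults (full mixing
    with a concentration-2 model) move 4-mer usage by a mean absolute
    frequency difference of roughly 0.002-0.003 against a concentration-20
    background — a divergence comparable to genomes of different genera,
    and strong enough for windowed signature profiling to localize.
    """
    other = random_order3_model(rng, concentration=concentration)
    mixed = (1 - strength) * model + strength * other
    return mixed / mixed.sum(axis=1, keepdims=True)


def default_mosaic_models(
    rng: np.random.Generator, concentration: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Default (background, donor) model pair for mosaic genomes.

    Both are independent Dirichlet draws at the same concentration, so the
    two chains are equally peaked — neither signature dominates the pooled
    whole-genome signature — while remaining mutually divergent. At
    concentration 3 the empirical 4-mer signature divergence is about
    0.002-0.003, comparable to genomes of different genera.
    """
    background = random_order3_model(rng, concentration)
    donor = random_order3_model(rng, concentration)
    return background, donor


def _validate_model(model: np.ndarray, name: str) -> np.ndarray:
    model = np.asarray(model, dtype=float)
    if model.shape != (64, 4):
        raise ValidationError(f"{name}: transition model must have shape (64, 4)")
    if (model < 0).any():
        raise ValidationError(f"{name}: negative transition probability")
    if not np.allclose(model.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError(f"{name}: transition rows must sum to 1")
    return model


def sample_order3_chain(
    model: np.ndarray, length: int, rng: np.random.Generator
) -> str:
    """Sample a sequence of ``length`` bases from an order-3 chain."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    cum = np.cumsum(model, axis=1)
    out = list(rng.choice(list(BASES), size=min(3, length)))
    state = 0
    for b in out:
        state = (state * 4 + BASES.index(b)) % 64
    u = rng.random(max(0, length - 3))
    for i in range(length - 3):
        nxt = int(np.searchsorted(cum[state], u[i], side="right"))
        nxt = min(nxt, 3)
        out.append(BASES[nxt])
        state = (state % 16) * 4 + nxt
    return "".join(out)


def signature_divergence(
    model_a: np.ndarray,
    model_b: np.ndarray,
    n_bases: int = 100_000,
    seed: int = 0,
) -> float:
    """Empirical mean absolute difference of 4-mer frequencies.

    Measured on ``n_bases`` sampled from each chain; used to check that a
    donor model is divergent enough (>= 0.002) to be detectable.
    """
    rng = np.random.default_rng(seed)
    fa = count_tetra(sample_order3_chain(model_a, n_bases, rng)).frequencies()
    fb = count_tetra(sample_order3_chain(model_b, n_bases, rng)).frequencies()
    return float(np.mean(np.abs(fa - fb)))


# ---------------------------------------------------------------------------
# mosaic genome (tetranucleotide anomaly target)


@dataclass
class MosaicSpec:
    """A background genome with a compositionally divergent insert."""

    background_length: int = 34_000
    insert_length: int = 10_000
    insert_position: int = 18_000  # 1-based start of the insert
    background_order3_model: np.ndarray | None = None
    donor_order3_model: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_length < 1:
            raise ValidationError("insert_length must be >= 1")
        if self.background_length < 4:
            raise ValidationError("background_length must be >= 4")
        if not (1 <= self.insert_position):
            raise ValidationError("insert_position must be >= 1")
        if self.insert_position + self.insert_length - 1 > self.background_length:
            raise ValidationError("insert does not fit inside the background")


def make_mosaic_genome(spec: MosaicSpec) -> tuple[GenomeSequence, dict]:
    """Sample a mosaic genome; truth gives the insert's 1-based span.

    The background is sampled from its order-3 chain; the segment
    ``[insert_position, insert_position + insert_length - 1]`` is replaced
    by a sample from the donor chain, so total length stays
    ``background_length``. Default models come from
    :func:`default_mosaic_models`.
    """
    rng = np.random.default_rng(spec.seed)
    bg_model = spec.background_order3_model
    donor_model = spec.donor_order3_model
    if bg_model is None and donor_model is None:
        bg_model, donor_model = default_mosaic_models(rng)
    elif bg_model is None:
        bg_model = random_order3_model(rng)
    elif donor_model is None:
        donor_model = perturb_order3_model(bg_model, rng)
    bg_model = _validate_model(bg_model, "background model")
    donor_model = _validate_model(donor_model, "donor model")

    background = sample_order3_chain(bg_model, spec.background_length, rng)
    insert = sample_order3_chain(donor_model, spec.insert_length, rng)
    s0 = spec.insert_position - 1
    residues = background[:s0] + insert + background[s0 + spec.insert_length :]
    genome = GenomeSequence(id=f"mosaic_seed{spec.seed}", residues=residues)
    truth = {
        "insert_start": spec.insert_position,
        "insert_end": spec.insert_position + spec.insert_length - 1,
    }
    return genome, truth


# ---------------------------------------------------------------------------
# replichore genome (GC-skew target)


@dataclass
class ReplichoreSpec:
    """Two replichores of opposite G/C excess around a planted origin."""

    length: int = 34_000
    origin_position: int = 11_000  # 1-based
    bias: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("length must be >= 1")
        if not (1 <= self.origin_position <= self.length):
            raise ValidationError("origin_position must lie inside the genome")
        if not (0 <= self.bias < 0.5):
            raise ValidationError("bias must be in [0, 0.5)")


def make_replichore_genome(spec: ReplichoreSpec) -> tuple[GenomeSequence, dict]:
    """Sample a linear genome whose cumulative GC skew dips at the origin.

    Bases are i.i.d. with P(G) - P(C) = -bias before the origin and +bias
    after it (A and T fixed at 0.25 each), so window skews average -bias
    then +bias and the cumulative curve is V-shaped with its minimum at
    the planted origin.
    """
    rng = np.random.default_rng(spec.seed)
    n_before = spec.origin_position - 1
    n_after = spec.length - n_before

    def _draw(n: int, g_minus_c: float) -> np.ndarray:
        p = np.array(
            [0.25, 0.25 - g_minus_c / 2, 0.25 + g_minus_c / 2, 0.25]
        )  # A, C, G, T
        return rng.choice(np.array(list(BASES)), size=n, p=p)

    before = _draw(n_before, -spec.bias)
    after = _draw(n_after, +spec.bias)
    residues = "".join(np.concatenate([before, after]))
    genome = GenomeSequence(id=f"replichore_seed{spec.seed}", residues=residues)
    return genome, {"origin_position": spec.origin_position}


# ---------------------------------------------------------------------------
# synteny pair (gene order + hit table target)


def make_synteny_pair(
    n_a: int,
    n_b: int,
    planted_blocks: list[tuple[int, int, str]],
    seed: int = 0,
) -> tuple[list[GeneRecord], list[GeneRecord], list[HitRecord], dict]:
    """Gene tables and a hit table realizing exactly a planted pattern.

    ``planted_blocks`` is a list of ``(start, n_syntenic, gap_pattern)``:
    the first syntenic gene sits at 1-based position ``start`` in A's
    order, and ``gap_pattern`` (e.g. ``"0,2,0,1"``) gives the number of
    non-syntenic A-genes between each pair of consecutive syntenic genes.
    Partners occupy consecutive positions in B, block after block. Planted
    pairs get bitscore 50, e-value 1e-20, alignment length 30; non-syntenic
    genes get no hits, so the called blocks must match the plan exactly.

    Returns ``(genes_a, genes_b, hits, truth)`` where truth lists each
    planted block's A index span, B index span and syntenic gene count.
    """
    rng = np.random.default_rng(seed)

    def _genes(prefix: str, n: int) -> list[GeneRecord]:
        genes = []
        pos = 1
        for i in range(1, n + 1):
            glen = int(rng.integers(300, 1200)) // 3 * 3
            genes.append(
                GeneRecord(
                    gene_id=f"{prefix}{i:04d}",
                    start=pos,
                    end=pos + glen - 1,
                    strand="+" if rng.random() < 0.8 else "-",
                    product="hypothetical protein",
                    aa_length=max(1, glen // 3 - 1),
                )
            )
            pos += glen + int(rng.integers(0, 200))
        return genes

    genes_a = _genes("A", n_a)
    genes_b = _genes("B", n_b)

    used_a: set[int] = set()
    hits: list[HitRecord] = []
    truth_blocks = []
    next_b = 1
    for start, n_syn, gap_pattern in planted_blocks:
        gaps = [int(x) for x in gap_pattern.split(",") if x != ""] if gap_pattern else []
        if len(gaps) != max(0, n_syn - 1):
            raise ValidationError(
                f"gap_pattern must have {n_syn - 1} entries, got {len(gaps)}"
            )
        a_positions = [start]
        for gap in gaps:
            a_positions.append(a_positions[-1] + gap + 1)
        if a_positions[-1] > n_a:
            raise ValidationError("planted block runs past the end of genome A")
        if any(p in used_a for p in a_positions):
            raise ValidationError("planted blocks overlap on genome A")
        used_a.update(a_positions)
        b_positions = list(range(next_b, next_b + n_syn))
        next_b += n_syn
        if b_positions[-1] > n_b:
            raise ValidationError("planted block runs past the end of genome B")
        for ai, bi in zip(a_positions, b_positions):
            qa, sb = genes_a[ai - 1], genes_b[bi - 1]
            hits.append(
                HitRecord(
                    query_id=qa.gene_id,
                    subject_id=sb.gene_id,
                    pct_identity=80.0,
                    aln_length=30,
                    mismatches=6,
                    gap_opens=0,
                    q_start=1,
                    q_end=30,
                    s_start=1,
                    s_end=30,
                    evalue=1e-20,
                    bitscore=50.0,
                )
            )
        truth_blocks.append(
            {
                "a_range": (a_positions[0], a_positions[-1]),
                "b_range": (b_positions[0], b_positions[-1]),
                "n_syntenic": n_syn,
            }
        )
    return genes_a, genes_b, hits, {"blocks": truth_blocks}


# ---------------------------------------------------------------------------
# recruitment tables (RBH target)


@dataclass
class RecruitSpec:
    """Planted per-ORF recruitment expressed as forward/reverse hit tables."""

    n_orfs: int = 20
    orf_aa_lengths: tuple[int, ...] | None = None
    rates: tuple[float, ...] | None = None  # expected recruited reads per ORF
    total_virome_reads: int = 1_000_000
    decoy_rate: float = 0.0
    reciprocity_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orfs < 1:
            raise ValidationError("n_orfs must be >= 1")
        if self.orf_aa_lengths is not None and len(self.orf_aa_lengths) != self.n_orfs:
            raise ValidationError("orf_aa_lengths must have n_orfs entries")
        if self.rates is not None:
            if len(self.rates) != self.n_orfs:
                raise ValidationError("rates must have n_orfs entries")
            if any(r < 0 for r in self.rates):
                raise ValidationError("rates must be >= 0")
        if not (0 <= self.decoy_rate <= 1):
            raise ValidationError("decoy_rate must be in [0, 1]")
        if not (0 <= self.reciprocity_noise <= 1):
            raise ValidationError("reciprocity_noise must be in [0, 1]")
        if self.total_virome_reads <= 0:
            raise ValidationError("total_virome_reads must be > 0")


def make_recruitment_tables(
    spec: RecruitSpec,
) -> tuple[list[HitRecord], list[HitRecord], list[GeneRecord], dict]:
    """Simulate forward/reverse hit tables with planted per-ORF counts.

    Per-ORF read counts are Poisson draws at the planted rates (default
    rate 10 per ORF). Each planted read normally yields one forward hit
    (ORF -> read) and one reverse hit (read -> ORF) with matching scores,
    so the reciprocal-best-hit filter recovers the truth exactly. A
    ``decoy_rate`` fraction of reads get a forward hit only (reciprocity
    unverifiable, so they are dropped); a ``reciprocity_noise`` fraction
    get their reverse best hit reassigned to a different ORF (reciprocity
    broken). Truth reports the full planted counts, before degradation.
    """
    rng = np.random.default_rng(spec.seed)
    aa_lengths = spec.orf_aa_lengths or tuple(
        int(x) for x in rng.integers(80, 600, size=spec.n_orfs)
    )
    rates = spec.rates if spec.rates is not None else (10.0,) * spec.n_orfs

    orfs = []
    pos = 1
    for i, aa in enumerate(aa_lengths, start=1):
        glen = (aa + 1) * 3
        orfs.append(
            GeneRecord(
                gene_id=f"ORF{i:03d}",
                start=pos,
                end=pos + glen - 1,
                strand="+",
                product="simulated protein",
                aa_length=aa,
            )
        )
        pos += glen + 20

    counts = rng.poisson(rates)
    forward: list[HitRecord] = []
    reverse: list[HitRecord] = []
    truth_counts = {o.gene_id: int(c) for o, c in zip(orfs, counts)}

    def _hit(q: str, s: str, bitscore: float) -> HitRecord:
        return HitRecord(
            query_id=q,
            subject_id=s,
            pct_identity=70.0,
            aln_length=60,
            mismatches=18,
            gap_opens=0,
            q_start=1,
            q_end=60,
            s_start=1,
            s_end=60,
            evalue=1e-15,
            bitscore=bitscore,
        )

    read_no = 0
    for orf, c in zip(orfs, counts):
        for _ in range(int(c)):
            read_no += 1
            read_id = f"READ{read_no:06d}"
            forward.append(_hit(orf.gene_id, read_id, 60.0))
            if rng.random() < spec.decoy_rate:
                continue  # decoy: no reverse hit, reciprocity unverifiable
            if spec.n_orfs > 1 and rng.random() < spec.reciprocity_noise:
                others = [o.gene_id for o in orfs if o.gene_id != orf.gene_id]
                wrong = others[int(rng.integers(len(others)))]
                reverse.append(_hit(read_id, wrong, 60.0))
            else:
                reverse.append(_hit(read_id, orf.gene_id, 60.0))

    truth = {"counts": truth_counts, "total_planted": int(counts.sum())}
    return forward, reverse, orfs, truth
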
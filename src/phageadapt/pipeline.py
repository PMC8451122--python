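"""One-call genome characterization tying the analysis stages together.

``characterize`` runs sequence statistics, the tetranucleotide correlation
profile with anomaly localization, and the GC-skew origin/terminus call on
a phage genome; synteny and recruitment stages run only when their inputs
are supplied. One TSV is written per track plus a JSON summary. Outputs
use fixed 6-significant-digit float formatting so re-running an identical
configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from phageadapt import io as pio
from phageadapt import recruitment as precruit
from phageadapt import skew as pskew
from phageadapt import synteny as psynteny
from phageadapt import tetra as ptetra

logger = logging.getLogger("phageadapt")

SUMMARY_SCHEMA_VERSION = 1


def _fmt(x: float) -> str:
    return f"{x:.6g}"


@dataclass
class RunConfig:
    """Inputs and parameters of a characterization run."""

    phage_fasta: str
    host_fasta: str | None = None
    genes_a: str | None = None
    genes_b: str | None = None
    synteny_hits: str | None = None
    recruit_forward: str | None = None
    recruit_reverse: str | None = None
    recruit_genes: str | None = None
    out_dir: str = "."
    tetra_window: int = 10_000
    tetra_step: int = 1_000
    tetra_strand: str = "forward"
    anomaly_k: float = 2.0
    skew_window: int = 100
    skew_step: int = 100
    synteny_min_aln: int = 10
    synteny_max_evalue: float = 1e-5
    synteny_min_run: int = 5
    synteny_max_gap: int = 4
    synteny_colinear: bool = False
    recruit_total_reads: int | None = None
    recruit_virome_id: str = "virome"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "tetra_window",
            "tetra_step",
            "skew_window",
            "skew_step",
            "synteny_min_aln",
            "synteny_min_run",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synteny_max_gap < 0:
            raise ValueError("synteny_max_gap must be >= 0")
        for name in (
            "phage_fasta",
            "host_fasta",
            "genes_a",
            "genes_b",
            "synteny_hits",
            "recruit_forward",
            "recruit_reverse",
            "recruit_genes",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @property
    def synteny_enabled(self) -> bool:
        return all((self.genes_a, self.genes_b, self.synteny_hits))

    @property
    def recruitment_enabled(self) -> bool:
        return all(
            (
                self.recruit_forward,
                self.recruit_reverse,
                self.recruit_genes,
                self.recruit_total_reads,
            )
        )


def characterize(config: RunConfig) -> dict:
    """Run all configured stages; write per-track TSVs and a JSON summary.

    Returns the summary dict (also written to ``summary.json``). Stages
    whose inputs are absent contribute null summary fields.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "length": None,
        "gc_fraction": None,
        "n_fragments": None,
        "min_r_self": None,
        "min_fragment_index": None,
        "dip_span": None,
        "origin_bp": None,
        "terminus_bp": None,
        "n_blocks": None,
        "orf_coverage": None,
    }

    logger.info("stage: sequence statistics")
    phage = pio.read_fasta(config.phage_fasta)[0]
    stats = pio.seq_stats(phage)
    summary["length"] = stats["length"]
    summary["gc_fraction"] = (
        None if stats["gc_fraction"] is None else float(_fmt(stats["gc_fraction"]))
    )

    logger.info("stage: tetranucleotide signature profile")
    host = pio.read_fasta(config.host_fasta)[0] if config.host_fasta else None
    profile = ptetra.signature_profile(
        phage,
        host=host,
        window_bp=config.tetra_window,
        step_bp=config.tetra_step,
        strand=config.tetra_strand,
    )
    anomaly = ptetra.locate_anomaly(profile, k=config.anomaly_k)
    summary["n_fragments"] = len(profile)
    summary["min_r_self"] = float(_fmt(anomaly["min_r_self"]))
    summary["min_fragment_index"] = anomaly["min_fragment_index"]
    summary["dip_span"] = (
        None if anomaly["dip_span"] is None else list(anomaly["dip_span"])
    )
    with open(out_dir / "tetra_profile.tsv", "w") as fh:
        cols = ["fragment_index", "center_bp", "r_self"]
        if profile.r_host is not None:
            cols.append("r_host")
        fh.write("\t".join(cols) + "\n")
        for i in range(len(profile)):
            row = [
                str(int(profile.fragment_index[i])),
                str(int(profile.fragment_center_bp[i])),
                _fmt(profile.r_self[i]),
            ]
            if profile.r_host is not None:
                row.append(_fmt(profile.r_host[i]))
            fh.write("\t".join(row) + "\n")

    logger.info("stage: GC skew")
    track = pskew.skew_track(
        phage, window_bp=config.skew_window, step_bp=config.skew_step
    )
    summary["origin_bp"] = track.origin_bp
    summary["terminus_bp"] = track.terminus_bp
    with open(out_dir / "gc_skew.tsv", "w") as fh:
        fh.write("position\tskew\tcumulative\n")
        for i in range(len(track)):
            fh.write(
                f"{int(track.positions[i])}\t{_fmt(track.skew[i])}\t"
                f"{_fmt(track.cumulative[i])}\n"
            )

    if config.synteny_enabled:
        logger.info("stage: synteny blocks")
        genes_a = pio.read_gene_table(config.genes_a)
        genes_b = pio.read_gene_table(config.genes_b)
        hits = pio.read_hit_table(config.synteny_hits)
        pairing = psynteny.pair_homologs(
            hits,
            genes_a,
            genes_b,
            min_aln_bp=config.synteny_min_aln,
            max_evalue=config.synteny_max_evalue,
        )
        blocks = psynteny.call_blocks(
            genes_a,
            genes_b,
            pairing,
            min_run=config.synteny_min_run,
            max_gap=config.synteny_max_gap,
            colinear=config.synteny_colinear,
        )
        summary["n_blocks"] = len(blocks)
        with open(out_dir / "synteny_blocks.tsv", "w") as fh:
            fh.write(
                "a_first\ta_last\tb_first\tb_last\tn_syntenic\tmax_internal_gap\n"
            )
            for b in blocks:
                fh.write(
                    f"{b.a_range[0]}\t{b.a_range[1]}\t{b.b_range[0]}\t"
                    f"{b.b_range[1]}\t{b.n_syntenic}\t{b.max_internal_gap}\n"
                )

    if config.recruitment_enabled:
        logger.info("stage: read recruitment")
        forward = pio.read_hit_table(config.recruit_forward)
        reverse = pio.read_hit_table(config.recruit_reverse)
        orfs = pio.read_gene_table(config.recruit_genes)
        pairs = precruit.rbb_filter(forward, reverse)
        table = precruit.recruitment_report(
            pairs,
            orfs,
            total_virome_reads=config.recruit_total_reads,
            virome_id=config.recruit_virome_id,
        )
        summary["orf_coverage"] = float(_fmt(table.orf_coverage))
        with open(out_dir / "recruitment.tsv", "w") as fh:
            fh.write("orf_id\taa_length\tn_reads_recruited\tabundance\n")
            for _, row in table.per_orf.iterrows():
                fh.write(
                    f"{row.orf_id}\t{row.aa_length}\t{row.n_reads_recruited}\t"
                    f"{_fmt(row.abundance)}\n"
                )

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
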
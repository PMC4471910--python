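"""Readers and writers for the external formats the pipeline touches.

Internally every coordinate is 0-based half-open on the forward strand of a
named chromosome.  Conversion to the 1-based inclusive convention of GFF3 (and
human-facing reports) happens only at the format boundary, here.  BED output is
0-based half-open per the BED standard, i.e. identical to the internal
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import normalize_dna


class FormatError(ValueError):
    """A file violates its format or an internal invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/scaffold: an uppercase sequence over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with an optional strand."""

    chrom_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom_id == other.chrom_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom_id != other.chrom_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases strictly between the two intervals (0 if touching/overlapping)."""
        if self.overlaps(other):
            return 0
        return max(other.start - self.end, self.start - other.end, 0)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom_id == other.chrom_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A gene with exons and optional UTR sub-features.

    Exons must be sorted, non-overlapping and contained in the gene interval;
    introns are derived as the gaps between consecutive exons.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    five_prime_utrs: list[GenomicInterval] = field(default_factory=list)
    three_prime_utrs: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.interval.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        for child in self.exons + self.five_prime_utrs + self.three_prime_utrs:
            if not self.interval.contains(child):
                raise FormatError(
                    f"gene {self.gene_id}: feature {child} outside gene span"
                )

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(
                    GenomicInterval(
                        self.interval.chrom_id, prev.end, nxt.start,
                        self.interval.strand,
                    )
                )
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, map_invalid_to_n: bool = False) -> list[GenomeSequence]:
    """Read FASTA into GenomeSequence records, preserving order.

    Sequences are uppercased; characters outside {A,C,G,T,N} raise a
    FormatError unless ``map_invalid_to_n`` maps them to N.  Duplicate ids and
    empty files are rejected.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: missing FASTA header (line 1)")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            seq = normalize_dna(str(rec.seq), map_invalid_to_n)
        except ValueError as exc:
            raise FormatError(f"{path}: record {rec.id}: {exc}") from exc
        records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.chrom_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "5'UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR", "three_prime_utr"}


def _to_interval(feature, strand=None) -> GenomicInterval:
    # GFF3 is 1-based inclusive; internal convention is 0-based half-open.
    return GenomicInterval(
        feature.seqid, feature.start - 1, feature.end, strand or feature.strand
    )


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene -> mRNA -> exon/UTR).

    When a gene carries several mRNAs only the first one listed is used, so
    each gene yields a single model.  Exon/UTR features attached directly to a
    gene (no mRNA level) are accepted too.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons, utr5, utr3 = [], [], []
        for child in db.children(parent, order_by="start"):
            iv = _to_interval(child, gene.strand)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype in _UTR5_TYPES:
                utr5.append(iv)
            elif child.featuretype in _UTR3_TYPES:
                utr3.append(iv)
            gene_iv = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
            if child.featuretype in {"exon"} | _UTR5_TYPES | _UTR3_TYPES:
                if not gene_iv.contains(iv):
                    raise FormatError(
                        f"feature {child.id or child.featuretype} outside span of "
                        f"gene {gene.id}"
                    )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=GenomicInterval(
                    gene.seqid, gene.start - 1, gene.end, gene.strand
                ),
                exons=exons,
                five_prime_utrs=utr5,
                three_prime_utrs=utr3,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR rows, 1-based inclusive)."""

    def row(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return "\t".join(
            [
                iv.chrom_id, "mitekit", ftype, str(iv.start + 1), str(iv.end),
                ".", iv.strand, ".", attrs,
            ]
        )

    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.interval.chrom_id, g.interval.start)):
        mrna_id = f"{g.gene_id}.1"
        lines.append(row(g.interval, "gene", f"ID={g.gene_id}"))
        lines.append(row(g.interval, "mRNA", f"ID={mrna_id};Parent={g.gene_id}"))
        for i, ex in enumerate(g.exons, 1):
            lines.append(row(ex, "exon", f"ID={mrna_id}.exon{i};Parent={mrna_id}"))
        for i, u in enumerate(g.five_prime_utrs, 1):
            lines.append(
                row(u, "five_prime_UTR", f"ID={mrna_id}.utr5.{i};Parent={mrna_id}")
            )
        for i, u in enumerate(g.three_prime_utrs, 1):
            lines.append(
                row(u, "three_prime_UTR", f"ID={mrna_id}.utr3.{i};Parent={mrna_id}")
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# element catalog (BED6 + TSV sidecar)
# ---------------------------------------------------------------------------

SIDECAR_COLUMNS = [
    "name", "chrom", "start", "end", "strand", "percent_identity",
    "query_coverage", "score",
    "tsd_left", "tsd_right", "tsd_duplicated", "tir_left", "tir_right",
    "tir_len", "tir_n_paired", "complete", "length_bp", "at_content",
    "max_at_run",
]


def write_catalog(elements, bed_path, tsv_path) -> None:
    """Write an element catalog as BED6 plus a TSV sidecar with structure calls.

    BED score is percent identity x 10 as an integer (so 100% -> 1000).
    """
    bed_lines, tsv_lines = [], ["\t".join(SIDECAR_COLUMNS)]
    for i, el in enumerate(elements, 1):
        iv = el.hit.interval
        name = f"elem{i:05d}"
        bed_lines.append(
            "\t".join(
                [
                    iv.chrom_id, str(iv.start), str(iv.end), name,
                    str(int(round(el.hit.percent_identity * 10))), iv.strand,
                ]
            )
        )
        tsd, tir = el.tsd, el.tir
        tsv_lines.append(
            "\t".join(
                str(x)
                for x in [
                    name, iv.chrom_id, iv.start, iv.end, iv.strand,
                    f"{el.hit.percent_identity:.4f}",
                    f"{el.hit.query_coverage:.6f}", el.hit.score,
                    tsd.left_seq if tsd else ".",
                    tsd.right_seq if tsd else ".",
                    int(tsd.is_duplicated) if tsd else 0,
                    tir.left_seq if tir else ".",
                    tir.right_seq if tir else ".",
                    tir.length if tir else 0,
                    tir.n_paired if tir else 0,
                    int(el.complete), el.length_bp,
                    f"{el.at_content:.6f}", el.max_at_run,
                ]
            )
        )
    with open(bed_path, "w") as fh:
        fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(tsv_lines) + "\n")


def read_catalog(tsv_path):
    """Read the TSV sidecar back into ElementRecord objects."""
    from .discovery import AlignmentHit, ElementRecord, TIRPair, TSDPair

    elements = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SIDECAR_COLUMNS:
            raise FormatError(f"{tsv_path}: unexpected catalog columns")
        for line in fh:
            f = dict(zip(SIDECAR_COLUMNS, line.rstrip("\n").split("\t")))
            iv = GenomicInterval(
                f["chrom"], int(f["start"]), int(f["end"]), f["strand"]
            )
            hit = AlignmentHit(
                interval=iv, strand=f["strand"],
                percent_identity=float(f["percent_identity"]),
                query_coverage=float(f["query_coverage"]), score=int(f["score"]),
            )
            tsd = (
                TSDPair(f["tsd_left"], f["tsd_right"])
                if f["tsd_left"] != "." else None
            )
            tir = (
                TIRPair(f["tir_left"], f["tir_right"])
                if f["tir_left"] != "." else None
            )
            elements.append(
                ElementRecord(
                    hit=hit, tsd=tsd, tir=tir, complete=bool(int(f["complete"])),
                    length_bp=int(f["length_bp"]), at_content=float(f["at_content"]),
                    max_at_run=int(f["max_at_run"]),
                )
            )
    return elements


def read_config(path) -> dict:
    """Flat key = value config (TOML subset); values parsed as TOML scalars."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
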
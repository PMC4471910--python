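"""Genomic context of element insertions.

Classifies each element relative to annotated genes (gene body / 5'- or
3'-flank distance bins / intergenic), summarizes category counts and
percentages, measures distances to UTRs, places element fragments carried by
transcripts into gene sub-features, and genotypes insertion presence/absence
across genomes from flanking anchor sequences (the in-silico analogue of a
flanking-primer PCR assay, where "product size" is the anchor-to-anchor
span).

Distances are nearest-edge to nearest-edge; flank bins are half-open
([0,1000), [1000,2000), [2000,3000)) and anything at 3000 bp or more is
intergenic.  Flank side (5' vs 3') follows the gene's strand only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._align import sw_affine
from ._util import revcomp, round_half_up
from .discovery import ElementRecord, TSDPair
from .io_core import GeneModel, GenomeSequence, GenomicInterval

CATEGORIES = [
    "gene",
    "five_flank_lt1k",
    "five_flank_1to2k",
    "five_flank_2to3k",
    "three_flank_lt1k",
    "three_flank_1to2k",
    "three_flank_2to3k",
    "intergenic",
]

SUB_FEATURES = ["intron", "exon", "five_utr", "three_utr"]


@dataclass(frozen=True)
class InsertionContext:
    element_id: str
    category: str
    distance_bp: int
    nearest_gene_id: Optional[str]
    sub_feature: Optional[str] = None


@dataclass
class ContextSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    n_total: int
    gene_rich_percent: float  # within 3 kb of a gene, gene body included


@dataclass
class LocusGenotype:
    locus_id: str
    calls: dict[str, str]  # genome id -> present | absent | no_data
    product_sizes: dict[str, Optional[int]]
    anchor_coords: dict[str, Optional[tuple[int, int]]]


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def _majority_sub_feature(element: GenomicInterval, gene: GeneModel) -> str:
    """Sub-feature label: intron when fully inside one, else by majority overlap."""
    for intron in gene.introns:
        if intron.contains(element):
            return "intron"
    overlaps = {
        "five_utr": sum(element.overlap_len(u) for u in gene.five_prime_utrs),
        "three_utr": sum(element.overlap_len(u) for u in gene.three_prime_utrs),
        "exon": sum(element.overlap_len(e) for e in gene.exons),
        "intron": sum(element.overlap_len(i) for i in gene.introns),
    }
    # UTR overlap is counted inside exon overlap; remove it so labels partition
    overlaps["exon"] -= overlaps["five_utr"] + overlaps["three_utr"]
    best = max(overlaps.items(), key=lambda kv: (kv[1], -SUB_FEATURES.index(kv[0])))
    return best[0] if best[1] > 0 else "exon"


def classify_context(
    element: ElementRecord | GenomicInterval,
    genes: Sequence[GeneModel],
    bins: tuple[int, int, int] = (1000, 2000, 3000),
    element_id: str = "element",
) -> InsertionContext:
    """Assign the element to one gene/flank/intergenic category.

    Overlap with a gene span wins outright (distance 0).  Otherwise the
    nearest gene (by edge-to-edge gap; ties toward the 5'-flank assignment,
    then the lower gene id) determines the side and bin.  Gaps of
    ``bins[2]`` (default 3000) or more — or no gene on the chromosome —
    are intergenic.
    """
    iv = element.hit.interval if isinstance(element, ElementRecord) else element
    here = [g for g in genes if g.interval.chrom_id == iv.chrom_id]
    if not here:
        return InsertionContext(element_id, "intergenic", bins[2], None)

    candidates = []
    for gene in here:
        if iv.overlaps(gene.interval):
            sub = _majority_sub_feature(iv, gene)
            return InsertionContext(element_id, "gene", 0, gene.gene_id, sub)
        gap = iv.gap_to(gene.interval)
        if gene.interval.strand == "+":
            side = "five" if iv.end <= gene.interval.start else "three"
        else:
            side = "five" if iv.start >= gene.interval.end else "three"
        candidates.append((gap, 0 if side == "five" else 1, gene.gene_id, side, gene))
    gap, _, gene_id, side, gene = min(candidates)
    if gap >= bins[2]:
        return InsertionContext(element_id, "intergenic", gap, gene_id)
    if gap < bins[0]:
        binlab = "lt1k"
    elif gap < bins[1]:
        binlab = "1to2k"
    else:
        binlab = "2to3k"
    return InsertionContext(element_id, f"{side}_flank_{binlab}", gap, gene_id)


def classify_catalog(
    elements: Sequence[ElementRecord],
    genes: Sequence[GeneModel],
    bins: tuple[int, int, int] = (1000, 2000, 3000),
) -> list[InsertionContext]:
    return [
        classify_context(el, genes, bins, element_id=f"elem{i:05d}")
        for i, el in enumerate(elements, 1)
    ]


def summarize_contexts(contexts: Sequence[InsertionContext]) -> ContextSummary:
    """Category counts and half-up one-decimal percentages, plus the
    "gene-rich" aggregate (everything but intergenic)."""
    if not contexts:
        raise ValueError("no contexts to summarize")
    counts = {cat: 0 for cat in CATEGORIES}
    for ctx in contexts:
        counts[ctx.category] += 1
    n = len(contexts)
    percentages = {
        cat: round_half_up(100.0 * c / n, 1) for cat, c in counts.items()
    }
    gene_rich = round_half_up(100.0 * (n - counts["intergenic"]) / n, 1)
    return ContextSummary(
        counts=counts, percentages=percentages, n_total=n,
        gene_rich_percent=gene_rich,
    )


def summarize_counts(counts: Mapping[str, int]) -> ContextSummary:
    """ContextSummary straight from per-category counts (e.g. a printed table)."""
    contexts = [
        InsertionContext(f"x{i}", cat, 0 if cat == "gene" else 1, None)
        for cat, c in counts.items()
        for i in range(c)
    ]
    return summarize_contexts(contexts)


def contexts_to_frame(contexts: Sequence[InsertionContext]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.element_id, c.category, c.distance_bp, c.nearest_gene_id,
             c.sub_feature)
            for c in contexts
        ],
        columns=["element_id", "category", "distance_bp", "nearest_gene",
                 "sub_feature"],
    )


# ---------------------------------------------------------------------------
# UTR distances
# ---------------------------------------------------------------------------

def utr_distance(
    element: ElementRecord | GenomicInterval, genes: Sequence[GeneModel]
) -> Optional[tuple[int, bool]]:
    """(distance to nearest annotated UTR, inside-UTR flag); None if the
    annotation carries no UTR features on the element's chromosome."""
    iv = element.hit.interval if isinstance(element, ElementRecord) else element
    utrs = [
        u
        for g in genes
        if g.interval.chrom_id == iv.chrom_id
        for u in g.five_prime_utrs + g.three_prime_utrs
    ]
    if not utrs:
        return None
    best = min(iv.gap_to(u) if not iv.overlaps(u) else 0 for u in utrs)
    within = any(iv.overlaps(u) for u in utrs)
    return best, within


# ---------------------------------------------------------------------------
# transcript fragment localization
# ---------------------------------------------------------------------------

def locate_fragment_in_transcript(
    est_seq: str,
    element_seq: str,
    gene_model: GeneModel,
    genome: GenomeSequence,
    min_block: int = 20,
    min_identity: float = 80.0,
    locus_margin: int = 1000,
) -> str:
    """Label the element-derived block of a transcript by gene sub-feature.

    The element-matching block of the EST is found by local alignment of the
    EST against the element (both orientations); that block is then placed on
    the genome around the gene locus, and labelled by majority overlap with
    the annotated sub-features (five_utr / three_utr / intron / cds).
    Returns "unplaced" when no confident block or placement exists.
    """
    best = None
    for query in (est_seq, revcomp(est_seq)):
        aln = sw_affine(query, element_seq)
        if best is None or aln.score > best[0].score:
            best = (aln, query)
    aln, oriented_est = best
    block = oriented_est[aln.a_start : aln.a_end]
    if len(block) < min_block or aln.percent_identity < min_identity:
        return "unplaced"

    giv = gene_model.interval
    wstart = max(0, giv.start - locus_margin)
    wend = min(len(genome.sequence), giv.end + locus_margin)
    window = genome.sequence[wstart:wend]
    placed = None
    for b in (block, revcomp(block)):
        g_aln = sw_affine(b, window)
        if placed is None or g_aln.score > placed.score:
            placed = g_aln
    span = (placed.b_end - placed.b_start)
    if span < min_block or placed.percent_identity < min_identity:
        return "unplaced"
    placed_iv = GenomicInterval(
        giv.chrom_id, wstart + placed.b_start, wstart + placed.b_end
    )
    overlaps = {
        "five_utr": sum(placed_iv.overlap_len(u) for u in gene_model.five_prime_utrs),
        "three_utr": sum(placed_iv.overlap_len(u) for u in gene_model.three_prime_utrs),
        "intron": sum(placed_iv.overlap_len(i) for i in gene_model.introns),
        "cds": sum(placed_iv.overlap_len(e) for e in gene_model.exons),
    }
    overlaps["cds"] -= overlaps["five_utr"] + overlaps["three_utr"]
    label, amount = max(
        overlaps.items(), key=lambda kv: (kv[1], kv[0])
    )
    return label if amount > 0 else "unplaced"


# ---------------------------------------------------------------------------
# locus genotyping
# ---------------------------------------------------------------------------

def _find_unique(haystack: str, needle: str) -> Optional[int]:
    """Start of the unique occurrence of needle, else None (absent or multiple)."""
    first = haystack.find(needle)
    if first == -1:
        return None
    if haystack.find(needle, first + 1) != -1:
        return None
    return first


def genotype_locus(
    genomes: Sequence[GenomeSequence],
    left_anchor: str,
    right_anchor: str,
    element_seq: str,
    locus_id: str = "locus",
    min_identity: float = 70.0,
    empty_gap_max: int = 50,
) -> LocusGenotype:
    """Call insertion presence/absence at an anchored locus per genome.

    Both anchors must occur exactly once, in order, on one strand of a
    genome; otherwise that genome is "no_data".  "present" requires the
    intervening segment to match the element above ``min_identity`` percent
    with a duplicated 3-bp TSD immediately inside the anchors; an intervening
    gap shorter than ``empty_gap_max`` bp is the pre-insertion allele
    ("absent").  The reported product size is the anchor-to-anchor span
    (in-silico band size).
    """
    if len(left_anchor) < 18 or len(right_anchor) < 18:
        raise ValueError("anchors must be at least 18 nt")
    calls: dict[str, str] = {}
    sizes: dict[str, Optional[int]] = {}
    coords: dict[str, Optional[tuple[int, int]]] = {}
    for genome in genomes:
        located = None
        for strand, seq in (("+", genome.sequence), ("-", revcomp(genome.sequence))):
            lpos = _find_unique(seq, left_anchor)
            rpos = _find_unique(seq, right_anchor)
            if lpos is None or rpos is None:
                continue
            if lpos + len(left_anchor) > rpos:
                continue
            located = (strand, seq, lpos, rpos)
            break
        if located is None:
            calls[genome.chrom_id] = "no_data"
            sizes[genome.chrom_id] = None
            coords[genome.chrom_id] = None
            continue
        strand, seq, lpos, rpos = located
        inner_start = lpos + len(left_anchor)
        inner = seq[inner_start:rpos]
        span = rpos + len(right_anchor) - lpos
        sizes[genome.chrom_id] = span
        coords[genome.chrom_id] = (lpos, rpos + len(right_anchor))
        if len(inner) < empty_gap_max:
            calls[genome.chrom_id] = "absent"
            continue
        aln = sw_affine(element_seq, inner)
        coverage = (aln.a_end - aln.a_start) / len(element_seq)
        tsd = TSDPair(
            inner[max(0, aln.b_start - 3) : aln.b_start],
            inner[aln.b_end : aln.b_end + 3],
        ) if aln.b_start >= 3 and aln.b_end + 3 <= len(inner) else None
        if (
            aln.percent_identity >= min_identity
            and coverage >= 0.5
            and tsd is not None
            and tsd.is_duplicated
        ):
            calls[genome.chrom_id] = "present"
        else:
            calls[genome.chrom_id] = "no_data"
    return LocusGenotype(
        locus_id=locus_id, calls=calls, product_sizes=sizes, anchor_coords=coords
    )
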
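"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study conditions the pipeline is meant for:
chromosomes with planted Tourist-like element copies (14-bp TIRs, 3-bp TSD
duplicated from the target site, an AT-rich interior with a long contiguous
A/T run), point-substitution divergence and optional 5'-truncation among
copies, gene models with exons/introns/UTRs placed at planned distances and
sub-features, bisulfite clone sets with per-context methylation rates and a
conversion-efficiency parameter, multi-genome insertion-polymorphism panels,
and transcripts carrying element fragments.

Every generator takes an explicit seed and is bitwise-deterministic under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import revcomp
from .io_core import GeneModel, GenomeSequence, GenomicInterval

BASES = np.array(list("ACGT"))

#: Family consensus TIR (Tourist-like, 14 bp).
DEFAULT_TIR = "GGGTCTGACTGGTT"


@dataclass
class FamilySpec:
    """Parameters of the simulated element family.

    The consensus is TIR + AT-rich core (containing one contiguous A/T run)
    + reverse-complement TIR.  Defaults mirror a mid-sized Tourist-like
    family: 545-bp elements, ~67% AT overall, a 270-bp A/T run.
    """

    tir: str = DEFAULT_TIR
    core_length: int = 517
    at_run_length: int = 270
    core_at_fraction: float = 0.67
    substitution_rate: float = 0.02
    truncation_probability: float = 0.0
    copies_per_chrom: int = 20
    tsd_motif: Optional[str] = None  # None: duplicate the target 3-mer as-is

    def __post_init__(self):
        if self.core_length < 10:
            raise ValueError("core too short (need >= 10 bp between the TIRs)")
        if self.at_run_length > self.core_length:
            raise ValueError("A/T run longer than the core")
        for r in (self.substitution_rate, self.truncation_probability):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def element_length(self) -> int:
        return 2 * len(self.tir) + self.core_length


@dataclass
class PlantedCopy:
    """Ground truth for one planted element copy (final genome coordinates)."""

    copy_id: str
    interval: GenomicInterval  # the element itself, TSDs excluded
    strand: str
    n_substitutions: int
    truncated: bool
    tsd: str
    sequence: str  # as written into the genome (forward strand)
    planned_category: Optional[str] = None
    planned_distance: Optional[int] = None
    planned_sub_feature: Optional[str] = None


@dataclass
class PlantingTruth:
    consensus: str
    copies: list[PlantedCopy] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome and consensus
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int = 2,
    chrom_len: int = 200_000,
    gc: float = 0.35,
    seed: int | None = None,
    prefix: str = "chr",
) -> list[GenomeSequence]:
    """I.i.d. random chromosomes at the stated GC content."""
    if n_chrom <= 0 or chrom_len <= 0:
        raise ValueError("n_chrom and chrom_len must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return [
        GenomeSequence(
            f"{prefix}{i + 1}",
            "".join(rng.choice(BASES, size=chrom_len, p=p)),
        )
        for i in range(n_chrom)
    ]


def make_consensus(spec: FamilySpec, seed: int | None = None) -> str:
    """Family consensus: TIR + AT-rich core with one A/T run + revcomp TIR."""
    rng = np.random.default_rng(seed)
    run = "".join(rng.choice(["A", "T"], size=spec.at_run_length))
    n_rest = spec.core_length - spec.at_run_length
    if n_rest > 0:
        rest_at = (spec.core_at_fraction * spec.core_length - spec.at_run_length) / n_rest
        rest_at = min(1.0, max(0.0, rest_at))
        p = np.array([rest_at / 2, (1 - rest_at) / 2, (1 - rest_at) / 2, rest_at / 2])
        rest = "".join(rng.choice(BASES, size=n_rest, p=p))
    else:
        rest = ""
    pos = int(rng.integers(0, len(rest) + 1))
    core = rest[:pos] + run + rest[pos:]
    return spec.tir + core + revcomp(spec.tir)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0:
        return seq, 0
    chars = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars), len(hits)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _spaced_positions(
    length: int, n: int, spacing: int, margin: int, rng: np.random.Generator
) -> list[int]:
    """n sorted positions in [margin, length - margin) pairwise >= spacing apart."""
    slack = length - 2 * margin - (n - 1) * spacing
    if n > 0 and slack < 0:
        raise ValueError(
            f"cannot place {n} copies with spacing {spacing} on {length} bp"
        )
    u = np.sort(rng.integers(0, slack + 1, size=n))
    return [int(margin + i * spacing + u[i]) for i in range(n)]


def plant_elements(
    genomes: Sequence[GenomeSequence],
    spec: FamilySpec,
    seed: int | None = None,
    consensus: str | None = None,
    min_spacing: int = 7800,
    margin: int = 4700,
) -> tuple[list[GenomeSequence], PlantingTruth]:
    """Insert element copies into genomes with TSD mechanics.

    Each insertion duplicates the 3-mer at the target site (or writes the
    forced ``spec.tsd_motif`` on both sides), inserts the possibly mutated
    and possibly 5'-truncated copy between the two triplets, and records the
    final coordinates as ground truth.  Substitutions spare the TSDs.
    ``min_spacing``/``margin`` keep loci far enough apart that downstream
    annotation plans cannot interfere with each other.
    """
    rng = np.random.default_rng(seed)
    if consensus is None:
        consensus = make_consensus(spec, seed=rng.integers(0, 2**31 - 1))
    truth = PlantingTruth(consensus=consensus)
    out_genomes: list[GenomeSequence] = []
    copy_no = 0
    for genome in genomes:
        sites = _spaced_positions(
            genome.length_bp, spec.copies_per_chrom, min_spacing, margin, rng
        )
        pieces: list[str] = []
        prev = 0
        offset = 0
        for p in sites:
            copy_no += 1
            seq = consensus
            truncated = bool(rng.random() < spec.truncation_probability)
            if truncated:
                cut = int(rng.integers(len(spec.tir) + 5, len(seq) // 2 + 1))
                seq = seq[cut:]
            seq, n_sub = _mutate(seq, spec.substitution_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            triplet = spec.tsd_motif or genome.sequence[p : p + 3]
            if "N" in triplet:
                triplet = "TAA"
            pieces.append(genome.sequence[prev:p])
            pieces.append(triplet + seq + triplet)
            elem_start = p + offset + 3
            truth.copies.append(
                PlantedCopy(
                    copy_id=f"copy{copy_no:04d}",
                    interval=GenomicInterval(
                        genome.chrom_id, elem_start, elem_start + len(seq), strand
                    ),
                    strand=strand,
                    n_substitutions=n_sub,
                    truncated=truncated,
                    tsd=triplet,
                    sequence=seq,
                )
            )
            prev = p + 3  # the original target triplet is consumed (duplicated)
            offset += len(seq) + 3
        pieces.append(genome.sequence[prev:])
        out_genomes.append(GenomeSequence(genome.chrom_id, "".join(pieces)))
    return out_genomes, truth


# ---------------------------------------------------------------------------
# annotation plans
# ---------------------------------------------------------------------------

_BIN_RANGES = {"lt1k": (100, 900), "1to2k": (1100, 1900), "2to3k": (2100, 2900)}


@dataclass(frozen=True)
class ContextPlan:
    category: str  # one of insertion_context.CATEGORIES
    distance: int  # planned edge-to-edge gap (0 for gene / intergenic)
    sub_feature: Optional[str] = None  # for category "gene"


def draw_context_plan(
    n: int,
    category_counts: dict[str, int],
    seed: int | None = None,
    intron_fraction_of_gene: float = 1.0,
) -> list[ContextPlan]:
    """A shuffled plan with exactly the requested per-category counts.

    Flank-bin distances are drawn uniformly inside the bin (clear of the bin
    edges); "gene" copies default to intronic placement.
    """
    if sum(category_counts.values()) != n:
        raise ValueError("category counts do not sum to n")
    rng = np.random.default_rng(seed)
    plans: list[ContextPlan] = []
    for cat, count in category_counts.items():
        for _ in range(count):
            if cat == "gene":
                sub = "intron" if rng.random() < intron_fraction_of_gene else "exon"
                plans.append(ContextPlan(cat, 0, sub))
            elif cat == "intergenic":
                plans.append(ContextPlan(cat, 0))
            else:
                binlab = cat.split("_")[-1]
                lo, hi = _BIN_RANGES[binlab]
                plans.append(ContextPlan(cat, int(rng.integers(lo, hi + 1))))
    order = rng.permutation(len(plans))
    return [plans[i] for i in order]


def _flank_gene(
    chrom: str, s: int, e: int, plan: ContextPlan, gene_id: str,
    gene_length: int, rng: np.random.Generator,
) -> GeneModel:
    """A gene at the planned gap from element [s, e), on the side and strand
    that realizes the planned 5'/3' assignment."""
    side_right = bool(rng.random() < 0.5)
    five = plan.category.startswith("five")
    if side_right:
        g0 = e + plan.distance
        g1 = g0 + gene_length
        strand = "+" if five else "-"
    else:
        g1 = s - plan.distance
        g0 = g1 - gene_length
        strand = "-" if five else "+"
    iv = GenomicInterval(chrom, g0, g1, strand)
    exons = [
        GenomicInterval(chrom, g0, g0 + 500, strand),
        GenomicInterval(chrom, g0 + 700, g1, strand),
    ]
    if strand == "+":
        utr5 = [GenomicInterval(chrom, g0, g0 + 150, strand)]
        utr3 = [GenomicInterval(chrom, g1 - 150, g1, strand)]
    else:
        utr5 = [GenomicInterval(chrom, g1 - 150, g1, strand)]
        utr3 = [GenomicInterval(chrom, g0, g0 + 150, strand)]
    return GeneModel(gene_id, iv, exons, utr5, utr3)


def _overlap_gene(
    chrom: str, s: int, e: int, sub: str, gene_id: str
) -> GeneModel:
    """A + strand gene containing element [s, e) in the planned sub-feature."""
    if sub == "intron":
        iv = GenomicInterval(chrom, s - 400, e + 400, "+")
        exons = [
            GenomicInterval(chrom, s - 400, s - 50, "+"),
            GenomicInterval(chrom, e + 50, e + 400, "+"),
        ]
        utr5 = [GenomicInterval(chrom, s - 400, s - 300, "+")]
        utr3 = [GenomicInterval(chrom, e + 300, e + 400, "+")]
    elif sub == "exon":
        iv = GenomicInterval(chrom, s - 300, e + 300, "+")
        exons = [GenomicInterval(chrom, s - 300, e + 300, "+")]
        utr5 = [GenomicInterval(chrom, s - 300, s - 200, "+")]
        utr3 = [GenomicInterval(chrom, e + 200, e + 300, "+")]
    elif sub == "five_utr":
        iv = GenomicInterval(chrom, s - 100, e + 1100, "+")
        exons = [
            GenomicInterval(chrom, s - 100, e + 100, "+"),
            GenomicInterval(chrom, e + 300, e + 1100, "+"),
        ]
        utr5 = [GenomicInterval(chrom, s - 100, e + 100, "+")]
        utr3 = [GenomicInterval(chrom, e + 1000, e + 1100, "+")]
    elif sub == "three_utr":
        iv = GenomicInterval(chrom, s - 1100, e + 100, "+")
        exons = [
            GenomicInterval(chrom, s - 1100, s - 300, "+"),
            GenomicInterval(chrom, s - 100, e + 100, "+"),
        ]
        utr5 = [GenomicInterval(chrom, s - 1100, s - 1000, "+")]
        utr3 = [GenomicInterval(chrom, s - 100, e + 100, "+")]
    else:
        raise ValueError(f"unknown sub-feature {sub!r}")
    return GeneModel(gene_id, iv, exons, utr5, utr3)


def generate_annotation(
    genomes: Sequence[GenomeSequence],
    truth: PlantingTruth,
    context_plan: Sequence[ContextPlan],
    seed: int | None = None,
    gene_length: int = 1200,
) -> list[GeneModel]:
    """Place a gene per planted copy so its true context equals its plan.

    Intergenic copies get no gene.  The plan is stored back into the truth
    records.  Raises (naming the copy) when a gene would not fit on the
    chromosome.
    """
    if len(context_plan) != len(truth.copies):
        raise ValueError("context plan length differs from planted copies")
    rng = np.random.default_rng(seed)
    lengths = {g.chrom_id: g.length_bp for g in genomes}
    genes: list[GeneModel] = []
    for i, (copy, plan) in enumerate(zip(truth.copies, context_plan), 1):
        copy.planned_category = plan.category
        copy.planned_distance = plan.distance
        copy.planned_sub_feature = plan.sub_feature
        if plan.category == "intergenic":
            continue
        s, e = copy.interval.start, copy.interval.end
        chrom = copy.interval.chrom_id
        gene_id = f"gene{i:04d}"
        if plan.category == "gene":
            gene = _overlap_gene(chrom, s, e, plan.sub_feature or "intron", gene_id)
        else:
            gene = _flank_gene(chrom, s, e, plan, gene_id, gene_length, rng)
        if gene.interval.start < 0 or gene.interval.end > lengths[chrom]:
            raise ValueError(
                f"copy {copy.copy_id}: planned gene does not fit on {chrom}"
            )
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# bisulfite clones
# ---------------------------------------------------------------------------

def simulate_bisulfite_clones(
    region: str,
    element_span: tuple[int, int],
    rates_by_context: dict[str, float] | None = None,
    flank_rate: float = 0.0,
    n_clones: int = 10,
    conversion_efficiency: float = 0.99,
    seed: int | None = None,
):
    """Bisulfite-converted clone sequences over a reference region.

    Inside ``element_span`` each cytosine is methylated with its context rate
    (defaults CG 0.8, CHG 0.4, CHH 0.1); flank cytosines use ``flank_rate``.
    Unmethylated cytosines read T with probability ``conversion_efficiency``
    (conversion failures read C); methylated cytosines always read C.

    Returns (BisulfiteCloneSet, truth) where truth maps each C position to a
    per-clone boolean methylation vector.
    """
    from .methylation import BisulfiteCloneSet, classify_cytosine_context

    if rates_by_context is None:
        rates_by_context = {"CG": 0.8, "CHG": 0.4, "CHH": 0.1}
    for r in list(rates_by_context.values()) + [flank_rate, conversion_efficiency]:
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if n_clones < 1:
        raise ValueError("need at least one clone")
    rng = np.random.default_rng(seed)
    c_positions = [i for i, b in enumerate(region) if b == "C"]
    contexts = {i: classify_cytosine_context(region, i) for i in c_positions}
    truth: dict[int, list[bool]] = {i: [] for i in c_positions}
    clones = []
    for ci in range(n_clones):
        chars = list(region)
        for i in c_positions:
            inside = element_span[0] <= i < element_span[1]
            rate = rates_by_context[contexts[i]] if inside else flank_rate
            methylated = bool(rng.random() < rate)
            truth[i].append(methylated)
            if not methylated and rng.random() < conversion_efficiency:
                chars[i] = "T"
        clones.append((f"clone{ci + 1:02d}", "".join(chars)))
    return (
        BisulfiteCloneSet(reference=region, clones=clones, element_span=element_span),
        truth,
    )


# ---------------------------------------------------------------------------
# polymorphism panel
# ---------------------------------------------------------------------------

def generate_polymorphism_panel(
    element_seq: str,
    pattern: dict[str, bool],
    seed: int | None = None,
    flank_len: int = 300,
    tsd: str = "TAA",
    anchor_len: int = 20,
    gc: float = 0.4,
):
    """Multi-genome locus panel: present alleles carry TSD+element+TSD, absent
    alleles the pre-insertion single TSD; flanks are shared across genomes.

    Returns (genomes, left_anchor, right_anchor).  The size difference
    between the two alleles is element length + 3 (the duplicated triplet).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _ in range(100):
        left = "".join(rng.choice(BASES, size=flank_len, p=p))
        right = "".join(rng.choice(BASES, size=flank_len, p=p))
        la, ra = left[-anchor_len:], right[:anchor_len]
        present = left + tsd + element_seq + tsd + right
        absent = left + tsd + right
        ok = all(
            s.count(a) == 1 and revcomp(s).count(a) == 0
            for s in (present, absent)
            for a in (la, ra)
        )
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw unique anchors")
    genomes = [
        GenomeSequence(gid, present if has else absent)
        for gid, has in pattern.items()
    ]
    return genomes, la, ra


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def generate_transcripts(
    genomes: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    retain_introns: Sequence[str] = (),
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Spliced transcript sequences from gene models.

    Genes listed in ``retain_introns`` keep their intronic sequence
    (intron-retention isoform), so fragments planted in introns appear in
    the transcript.  Minus-strand transcripts are reverse-complemented to
    mRNA orientation.
    """
    by_chrom = {g.chrom_id: g.sequence for g in genomes}
    out = []
    for gene in genes:
        seq = by_chrom[gene.interval.chrom_id]
        if gene.gene_id in set(retain_introns):
            parts = [seq[gene.interval.start : gene.interval.end]]
        else:
            parts = [seq[e.start : e.end] for e in gene.exons]
        t = "".join(parts)
        if gene.interval.strand == "-":
            t = revcomp(t)
        out.append((f"{gene.gene_id}.t1", t))
    return out
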
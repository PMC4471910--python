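"""Find and structurally validate MITE insertions in genome sequences.

A query element (typically a family consensus) is searched against each
chromosome by seed-and-extend local alignment: exact shared k-mers nominate
candidate regions, which are then aligned with the full affine-gap
Smith–Waterman kernel so the reported hit equals the optimal local alignment
in that region.  Each hit is refined into an :class:`ElementRecord` by
searching the paper-typical structural signals of Tourist-like MITEs: a 3-bp
target-site duplication (TSD, canonically TAA) flanking the insertion, a
terminal inverted repeat (TIR) pair at the element ends, and composition
statistics of the AT-rich interior.  A Nussinov base-pair-maximization folder
supports the TIR stem-loop and miRNA-precursor assessments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._align import LocalAlignment, sw_affine
from ._util import max_at_run, at_content, pairs_wc, revcomp
from .io_core import GenomeSequence, GenomicInterval


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    """A local-alignment hit in genome-forward coordinates."""

    interval: GenomicInterval
    strand: str
    percent_identity: float
    query_coverage: float
    score: int

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query_coverage outside [0, 1]")


@dataclass(frozen=True)
class TSDPair:
    """The two 3-nt windows immediately flanking a putative insertion."""

    left_seq: str
    right_seq: str

    @property
    def is_duplicated(self) -> bool:
        return (
            self.left_seq == self.right_seq
            and "N" not in self.left_seq
            and len(self.left_seq) == 3
        )


@dataclass(frozen=True)
class TIRPair:
    """Terminal inverted repeat candidate: element prefix vs suffix."""

    left_seq: str
    right_seq: str

    def __post_init__(self):
        if len(self.left_seq) != len(self.right_seq):
            raise ValueError("TIR arms must have equal length")

    @property
    def length(self) -> int:
        return len(self.left_seq)

    @property
    def n_paired(self) -> int:
        # left[i] pairs with right[L-1-i], i.e. with reverse(right)[i]
        return sum(
            pairs_wc(a, b) for a, b in zip(self.left_seq, self.right_seq[::-1])
        )

    @property
    def n_mismatch(self) -> int:
        return self.length - self.n_paired


@dataclass
class ElementRecord:
    """A located element insertion with its structural validation."""

    hit: AlignmentHit
    tsd: Optional[TSDPair]
    tir: Optional[TIRPair]
    complete: bool
    length_bp: int
    at_content: float
    max_at_run: int


@dataclass(frozen=True)
class HairpinFold:
    """Result of base-pair maximization folding."""

    n_pairs: int
    structure: str
    min_loop: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        stack, out = [], []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        return sorted(out)


# ---------------------------------------------------------------------------
# seed-and-extend scan
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _candidate_windows(
    genome_seq: str, query: str, k: int, pad: int = 30
) -> list[tuple[int, int]]:
    """Regions of the genome nominated by exact shared k-mers.

    Seeds are grouped into windows wide enough to contain the full query
    alignment around any seed; overlapping windows are merged so each
    candidate locus is aligned once.
    """
    qindex = _kmer_positions(query, k)
    qlen = len(query)
    spans = []
    for g in range(len(genome_seq) - k + 1):
        kmer = genome_seq[g : g + k]
        hits = qindex.get(kmer)
        if not hits:
            continue
        for q in hits:
            start = max(0, g - q - pad)
            end = min(len(genome_seq), g + (qlen - q) + pad)
            spans.append((start, end))
    spans.sort()
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def seed_extend_scan(
    genomes: Sequence[GenomeSequence],
    query_seq: str,
    k: int = 12,
    min_identity: float = 70.0,
    min_coverage: float = 0.5,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> list[AlignmentHit]:
    """Scan genomes for local-alignment hits of the query on both strands.

    Exact shared k-mers nominate candidate windows; each window is resolved
    with optimal affine-gap local alignment of the full query, so hit
    intervals and identities match a full Smith–Waterman run over the same
    region.  Hits below ``min_identity`` (percent) or ``min_coverage``
    (fraction of the query aligned) are dropped; overlapping same-strand hits
    keep the best score (ties: leftmost start, then + strand).
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(query_seq) < k:
        raise ValueError("query shorter than k")
    hits: list[AlignmentHit] = []
    for genome in genomes:
        for strand, q in (("+", query_seq), ("-", revcomp(query_seq))):
            for wstart, wend in _candidate_windows(genome.sequence, q, k):
                window = genome.sequence[wstart:wend]
                aln = sw_affine(q, window, match, mismatch, gap_open, gap_extend)
                if aln.n_columns == 0:
                    continue
                coverage = (aln.a_end - aln.a_start) / len(q)
                identity = aln.percent_identity
                if identity < min_identity or coverage < min_coverage:
                    continue
                interval = GenomicInterval(
                    genome.chrom_id, wstart + aln.b_start, wstart + aln.b_end,
                    strand,
                )
                hits.append(
                    AlignmentHit(interval, strand, identity, coverage, aln.score)
                )
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Among overlapping same-strand hits on a chromosome keep the best score;
    ties broken by leftmost start then + strand."""
    order = sorted(
        hits,
        key=lambda h: (-h.score, h.interval.chrom_id, h.interval.start,
                       0 if h.strand == "+" else 1),
    )
    kept: list[AlignmentHit] = []
    for h in order:
        if any(
            h.strand == other.strand and h.interval.overlaps(other.interval)
            for other in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval.chrom_id, h.interval.start))
    return kept


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def detect_tsd(genome: GenomeSequence, interval: GenomicInterval) -> TSDPair:
    """The 3-nt windows immediately left and right of the interval.

    Duplication is exact triplet equality with no N; the canonical-motif
    filter (e.g. TAA for Tourist-like families) is applied separately by
    :func:`tsd_passes`.
    """
    if interval.start < 3 or interval.end + 3 > len(genome.sequence):
        raise ValueError(
            f"interval {interval} has <3 bp of flank for TSD detection"
        )
    left = genome.sequence[interval.start - 3 : interval.start]
    right = genome.sequence[interval.end : interval.end + 3]
    return TSDPair(left, right)


def tsd_passes(pair: TSDPair, motif: str | None = None) -> bool:
    """Duplication call, optionally requiring the canonical motif."""
    if not pair.is_duplicated:
        return False
    return motif is None or pair.left_seq == motif.upper()


def detect_tir(
    element_seq: str,
    min_len: int = 10,
    max_len: int = 20,
    max_mismatch: int = 4,
) -> Optional[TIRPair]:
    """Best terminal-inverted-repeat call for an element sequence.

    For each arm length L in [min_len, max_len] the element prefix of length
    L is paired against the reverse of the suffix of length L, counting
    Watson–Crick complementary positions.  Among lengths whose mismatch count
    is within ``max_mismatch`` the call maximizes the number of paired
    positions, breaking ties toward fewer mismatches (shorter arms); None if
    no length qualifies.
    """
    if len(element_seq) < 2 * min_len:
        return None
    best: Optional[TIRPair] = None
    for L in range(max_len, min_len - 1, -1):
        if 2 * L > len(element_seq):
            continue
        pair = TIRPair(element_seq[:L], element_seq[-L:])
        if pair.n_mismatch > max_mismatch:
            continue
        if best is None or (pair.n_paired, -pair.n_mismatch) > (
            best.n_paired, -best.n_mismatch
        ):
            best = pair
    return best


def fold_max_pairs(seq: str, min_loop: int = 3, allow_gu: bool = False) -> HairpinFold:
    """Base-pair maximization (Nussinov) with a minimum hairpin loop.

    Pairs are Watson–Crick (optionally G·U wobble); a pair (i, j) requires
    j - i - 1 >= min_loop unpaired-capable span between them.  Returns the
    maximal pair count and one deterministic traceback as dot-bracket.
    """
    n = len(seq)
    if n > 2000:
        raise ValueError("sequence too long for quadratic folding (max 2000)")

    def can_pair(i: int, j: int) -> bool:
        a, b = seq[i], seq[j]
        if pairs_wc(a, b):
            return True
        return allow_gu and {a, b} == {"G", "T"}

    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            for kk in range(i, j - min_loop):
                paired = (
                    (dp[i][kk - 1] if kk > i else 0)
                    + 1
                    + (dp[kk + 1][j - 1] if kk + 1 <= j - 1 else 0)
                )
                if can_pair(kk, j) and paired > best:
                    best = paired
            dp[i][j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j > i:
            if dp[i][j] == (dp[i][j - 1] if j - 1 >= i else 0):
                j -= 1
                continue
            for kk in range(i, j - min_loop):
                if not can_pair(kk, j):
                    continue
                paired = (
                    (dp[i][kk - 1] if kk > i else 0)
                    + 1
                    + (dp[kk + 1][j - 1] if kk + 1 <= j - 1 else 0)
                )
                if paired == dp[i][j]:
                    structure[kk] = "("
                    structure[j] = ")"
                    if kk > i:
                        traceback(i, kk - 1)
                    i, j = kk + 1, j - 1
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")

    if n:
        traceback(0, n - 1)
    n_pairs = dp[0][n - 1] if n else 0
    return HairpinFold(n_pairs=n_pairs, structure="".join(structure), min_loop=min_loop)


# ---------------------------------------------------------------------------
# element assembly
# ---------------------------------------------------------------------------

def assemble_element(
    genome: GenomeSequence,
    hit: AlignmentHit,
    refine_window: int = 6,
    tir_min_len: int = 10,
    tir_max_len: int = 20,
    max_tir_mismatch: int = 4,
    min_tir_paired: int = 10,
    tsd_motif: str | None = None,
    completeness: str = "tsd+tir",
) -> ElementRecord:
    """Refine hit boundaries and classify completeness.

    Every boundary placement within ±``refine_window`` bp of each hit edge is
    scored lexicographically by (TSD duplicated, TIR qualifies, smallest
    boundary shift, TIR paired positions); the winner defines the element
    interval.  A TIR qualifies when its mismatch count is within
    ``max_tir_mismatch`` and it pairs at least ``min_tir_paired`` positions —
    the paired-count floor keeps chance pairing in AT-rich interiors from
    qualifying, and 10 is the family TIR's own pairing level (10 of 14).
    Preferring the smallest shift over raw paired count matters because a
    duplicated TSD pulled into the arms always adds chance pairings, so a
    pure paired-count objective drifts outward systematically.

    ``completeness`` is "tsd+tir" (duplicated TSD and a qualifying TIR) or
    "tsd" (duplicated TSD alone).
    """
    if completeness not in ("tsd+tir", "tsd"):
        raise ValueError("completeness must be 'tsd+tir' or 'tsd'")
    seqlen = len(genome.sequence)
    best_key = None
    best = None
    for dl in range(-refine_window, refine_window + 1):
        start = hit.interval.start + dl
        if start < 3 or start >= hit.interval.end:
            continue
        for dr in range(-refine_window, refine_window + 1):
            end = hit.interval.end + dr
            if end <= start or end + 3 > seqlen:
                continue
            interval = GenomicInterval(
                genome.chrom_id, start, end, hit.interval.strand
            )
            tsd = detect_tsd(genome, interval)
            element_seq = genome.sequence[start:end]
            oriented = element_seq if hit.strand == "+" else revcomp(element_seq)
            tir = detect_tir(oriented, tir_min_len, tir_max_len, max_tir_mismatch)
            qualifies = tir is not None and tir.n_paired >= min_tir_paired
            key = (
                int(tsd_passes(tsd, tsd_motif)),
                int(qualifies),
                -(abs(dl) + abs(dr)),  # prefer the original boundary
                tir.n_paired if tir else 0,
                -dl,
            )
            if best_key is None or key > best_key:
                best_key = key
                best = (interval, tsd, tir, element_seq, qualifies)
    if best is None:
        raise ValueError(f"hit {hit.interval} leaves no room for flanks")
    interval, tsd, tir, element_seq, tir_ok = best
    has_tsd = tsd_passes(tsd, tsd_motif)
    complete = has_tsd and (completeness == "tsd" or tir_ok)
    refined_hit = AlignmentHit(
        interval=interval,
        strand=hit.strand,
        percent_identity=hit.percent_identity,
        query_coverage=hit.query_coverage,
        score=hit.score,
    )
    return ElementRecord(
        hit=refined_hit,
        tsd=tsd,
        tir=tir,
        complete=complete,
        length_bp=interval.length,
        at_content=at_content(element_seq),
        max_at_run=max_at_run(element_seq),
    )


def scan_and_assemble(
    genomes: Sequence[GenomeSequence],
    query_seq: str,
    k: int = 12,
    min_identity: float = 70.0,
    min_coverage: float = 0.5,
    **assemble_kwargs,
) -> list[ElementRecord]:
    """Convenience pipeline: scan, then assemble every hit."""
    hits = seed_extend_scan(
        genomes, query_seq, k=k, min_identity=min_identity,
        min_coverage=min_coverage,
    )
    by_chrom = {g.chrom_id: g for g in genomes}
    return [
        assemble_element(by_chrom[h.interval.chrom_id], h, **assemble_kwargs)
        for h in hits
    ]
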
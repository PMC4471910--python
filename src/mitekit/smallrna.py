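"""Match small RNAs against element interiors and transcripts.

A mature small-RNA query (18-30 nt; U read as T) is slid over both strands of
an element, reporting every window within the mismatch budget in the
element's 1-based inclusive coordinates.  A matched neighborhood can then be
assessed as a miRNA-precursor candidate by base-pair-maximization folding of
a window anchored at the match: the assessment passes when the fold reaches
the pairing threshold and the mature match lies on one arm of the stem (no
base pair joins two positions inside the match).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from ._util import normalize_dna, revcomp
from .discovery import HairpinFold, fold_max_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmallRNAMatch:
    element_id: str
    query_id: str
    start: int  # 1-based inclusive, element forward coordinates
    end: int  # 1-based inclusive
    strand: str
    n_mismatch: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PrecursorAssessment:
    window_start: int  # 1-based inclusive in the element
    window_end: int
    fold: HairpinFold
    passes: bool


def find_matches(
    element_seq: str,
    small_rna: str,
    max_mismatch: int = 1,
    element_id: str = "element",
    query_id: str = "query",
) -> list[SmallRNAMatch]:
    """All sliding-window matches of the query on both element strands.

    Mismatches are Hamming distances (no indels); N never matches.  Minus
    strand hits are reported in element-forward coordinates.
    """
    query = normalize_dna(small_rna)
    if not 18 <= len(query) <= 30:
        raise ValueError("small-RNA query must be 18-30 nt")
    element = normalize_dna(element_seq)
    qlen, elen = len(query), len(element)
    out: list[SmallRNAMatch] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for off in range(elen - qlen + 1):
            window = element[off : off + qlen]
            mm = sum(
                a != b or a == "N" for a, b in zip(window, q)
            )
            if mm <= max_mismatch:
                out.append(
                    SmallRNAMatch(
                        element_id=element_id,
                        query_id=query_id,
                        start=off + 1,
                        end=off + qlen,
                        strand=strand,
                        n_mismatch=mm,
                    )
                )
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def assess_precursor(
    element_seq: str,
    match: SmallRNAMatch,
    window: int = 120,
    min_pairs: int = 16,
    min_loop: int = 3,
) -> PrecursorAssessment:
    """Fold the window starting at the match 5' end and test for a stem-loop.

    The window spans the match plus downstream sequence (``window`` nt in
    total; truncated with a warning at the element end).  Passing requires
    ``min_pairs`` base pairs in the maximal fold and the mature match on a
    single arm: no pair of the traceback structure may have both ends inside
    the match.
    """
    element = normalize_dna(element_seq)
    start0 = match.start - 1
    if not 0 <= start0 < len(element):
        raise ValueError("match outside element")
    end0 = start0 + window
    if end0 > len(element):
        logger.warning(
            "precursor window truncated from %d to %d nt at element end",
            window, len(element) - start0,
        )
        end0 = len(element)
    sub = element[start0:end0]
    fold = fold_max_pairs(sub, min_loop=min_loop)
    match_lo, match_hi = 0, match.end - match.start  # window-local, inclusive
    self_paired = any(
        match_lo <= i <= match_hi and match_lo <= j <= match_hi
        for i, j in fold.pairs
    )
    passes = fold.n_pairs >= min_pairs and not self_paired
    return PrecursorAssessment(
        window_start=start0 + 1, window_end=end0, fold=fold, passes=passes
    )


def match_transcripts(
    transcripts: Sequence[tuple[str, str]],
    small_rna: str,
    max_mismatch: int = 0,
    query_id: str = "query",
) -> tuple[dict[str, list[SmallRNAMatch]], int]:
    """Per-transcript match lists plus the count of transcripts with at least
    one perfect (0-mismatch) match."""
    per: dict[str, list[SmallRNAMatch]] = {}
    n_perfect = 0
    for label, seq in transcripts:
        matches = find_matches(
            seq, small_rna, max_mismatch=max_mismatch,
            element_id=label, query_id=query_id,
        )
        per[label] = matches
        if any(m.n_mismatch == 0 for m in matches):
            n_perfect += 1
    return per, n_perfect
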
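"""Bisulfite methylation calling over an element and its flanks.

Sanger-style clone sequences of a bisulfite-converted region are aligned to
the untreated reference with a conversion-aware global alignment: a reference
C pairing with clone C (methylated, i.e. protected from conversion) or clone
T (converted) costs nothing, while any other substitution is penalized.  Per
reference cytosine the methylated/total clone counts give the methylation
level; cytosines are classified into the plant contexts CG, CHG and CHH
(H = A, C or T).  Only the assayed strand is called — clone sequencing reads
one strand.  A known-unmethylated control region estimates conversion
efficiency; runs below the efficiency threshold flag all calls as
low-confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._align import nw_matrix, encode

logger = logging.getLogger(__name__)


@dataclass
class BisulfiteCloneSet:
    """A reference region (untreated genomic strand) plus converted clones."""

    reference: str
    clones: list[tuple[str, str]]  # (label, converted sequence)
    element_span: Optional[tuple[int, int]] = None  # 0-based half-open in reference
    strand: str = "+"

    def __post_init__(self):
        if not self.clones:
            raise ValueError("clone set must contain at least one clone")


@dataclass
class MethylationCall:
    position: int  # reference coordinate of the C
    context: str  # CG | CHG | CHH
    n_methylated: int
    n_total: int
    region: str = "element"  # element | flank

    @property
    def level(self) -> float:
        return self.n_methylated / self.n_total if self.n_total else float("nan")


@dataclass
class ConversionControl:
    control_id: str
    n_unconverted_c: int
    n_total_c: int

    @property
    def efficiency(self) -> float:
        if self.n_total_c == 0:
            return 1.0
        return 1.0 - self.n_unconverted_c / self.n_total_c


@dataclass
class MethylationReport:
    calls: list[MethylationCall]
    n_clones_used: int
    n_clones_rejected: int
    region_levels: dict[str, float] = field(default_factory=dict)
    context_levels: dict[str, float] = field(default_factory=dict)
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# conversion-aware alignment
# ---------------------------------------------------------------------------

def _bisulfite_score_matrix() -> np.ndarray:
    """5x5 scores (A,C,G,T,N): match 0, mismatch -1, and ref C vs clone T 0."""
    w = np.full((5, 5), -1, dtype=np.int64)
    for i in range(4):
        w[i, i] = 0
    w[4, :] = -1
    w[:, 4] = -1
    w[1, 3] = 0  # ref C read as clone T: bisulfite conversion, no penalty
    return w


def align_clone(
    reference: str, clone: str, gap: int = -2
) -> tuple[int, list[Optional[str]], float]:
    """Conversion-aware global alignment of one clone to the reference.

    Returns (score, per-reference-position clone base or None for a gap,
    conversion-aware identity).  Identity counts columns where the clone base
    equals the reference base or is the C->T conversion of a reference C.
    """
    if not 0.8 * len(reference) <= len(clone) <= 1.2 * len(reference):
        raise ValueError("clone length outside ±20% of the reference")
    w = _bisulfite_score_matrix()
    S = w[np.ix_(encode(reference), encode(clone))]
    score, path = nw_matrix(S, gap)
    pairing: list[Optional[str]] = [None] * len(reference)
    n_cols = n_ok = 0
    for i, j in path:
        n_cols += 1
        if i is not None and j is not None:
            pairing[i] = clone[j]
            rb, cb = reference[i], clone[j]
            if rb == cb and rb != "N" or (rb == "C" and cb == "T"):
                n_ok += 1
    identity = 100.0 * n_ok / n_cols if n_cols else 0.0
    return score, pairing, identity


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_cytosine_context(reference: str, position: int) -> str:
    """CG / CHG / CHH context of the C at ``position`` on the assayed strand.

    Near the region end the available bases decide; if the context cannot be
    determined (sequence runs out, or N downstream) the call falls back to
    CHH.
    """
    if reference[position] != "C":
        raise ValueError(f"position {position} is not a C")
    nxt = reference[position + 1] if position + 1 < len(reference) else None
    nxt2 = reference[position + 2] if position + 2 < len(reference) else None
    if nxt == "G":
        return "CG"
    if nxt in ("A", "C", "T") and nxt2 == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_methylation(
    clone_set: BisulfiteCloneSet,
    min_clone_identity: float = 80.0,
    gap: int = -2,
) -> MethylationReport:
    """Per-cytosine methylation calls over the reference region.

    A clone column counts as methylated when it shows C, converted when it
    shows T; gaps and other bases are excluded from that clone's tally.
    Clones under the conversion-aware identity threshold are rejected with a
    warning.  Region aggregates (element vs flank, by ``element_span``) and
    per-context aggregates are sum(methylated)/sum(total) weighted levels.
    """
    ref = clone_set.reference
    pairings = []
    n_rejected = 0
    for label, clone in clone_set.clones:
        _, pairing, identity = align_clone(ref, clone, gap)
        if identity < min_clone_identity:
            logger.warning(
                "clone %s rejected: conversion-aware identity %.1f%% < %.1f%%",
                label, identity, min_clone_identity,
            )
            n_rejected += 1
            continue
        pairings.append(pairing)
    if not pairings:
        raise ValueError("no clones accepted")

    span = clone_set.element_span
    calls: list[MethylationCall] = []
    for pos, base in enumerate(ref):
        if base != "C":
            continue
        n_meth = n_total = 0
        for pairing in pairings:
            b = pairing[pos]
            if b == "C":
                n_meth += 1
                n_total += 1
            elif b == "T":
                n_total += 1
        region = "element"
        if span is not None:
            region = "element" if span[0] <= pos < span[1] else "flank"
        calls.append(
            MethylationCall(
                position=pos,
                context=classify_cytosine_context(ref, pos),
                n_methylated=n_meth,
                n_total=n_total,
                region=region,
            )
        )

    def weighted(subset: list[MethylationCall]) -> float:
        tot = sum(c.n_total for c in subset)
        return sum(c.n_methylated for c in subset) / tot if tot else float("nan")

    region_levels = {
        reg: weighted([c for c in calls if c.region == reg])
        for reg in ("element", "flank")
        if any(c.region == reg for c in calls)
    }
    context_levels = {
        ctx: weighted([c for c in calls if c.context == ctx])
        for ctx in ("CG", "CHG", "CHH")
        if any(c.context == ctx for c in calls)
    }
    return MethylationReport(
        calls=calls,
        n_clones_used=len(pairings),
        n_clones_rejected=n_rejected,
        region_levels=region_levels,
        context_levels=context_levels,
    )


def conversion_efficiency(
    control_set: BisulfiteCloneSet,
    control_id: str = "control",
    min_clone_identity: float = 80.0,
) -> ConversionControl:
    """Conversion efficiency from a known-unmethylated control region.

    Every clone C opposite a reference C is an unconverted cytosine;
    efficiency = 1 - unconverted / total informative cytosine calls.
    """
    report = call_methylation(control_set, min_clone_identity)
    n_unconverted = sum(c.n_methylated for c in report.calls)
    n_total = sum(c.n_total for c in report.calls)
    return ConversionControl(
        control_id=control_id, n_unconverted_c=n_unconverted, n_total_c=n_total
    )


def apply_conversion_control(
    report: MethylationReport,
    control: ConversionControl,
    min_efficiency: float = 0.95,
) -> MethylationReport:
    """Flag a report as low-confidence when the control conversion efficiency
    falls below the threshold."""
    if control.efficiency < min_efficiency:
        logger.warning(
            "conversion efficiency %.3f below %.3f: flagging calls",
            control.efficiency, min_efficiency,
        )
        report.low_confidence = True
    return report


def report_to_rows(report: MethylationReport) -> list[dict]:
    confidence = "low" if report.low_confidence else "ok"
    return [
        {
            "position": c.position,
            "context": c.context,
            "n_meth": c.n_methylated,
            "n_total": c.n_total,
            "level": c.level,
            "region": c.region,
            "confidence": confidence,
        }
        for c in report.calls
    ]
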
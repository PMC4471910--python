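"""Family-level summaries of an element catalog.

Per-chromosome densities (elements per Mb), composition summaries of the
complete copies, the length vs AT-content correlation, the TIR consensus
frequency matrix (text pictogram), and an in-silico chromosome map.
Mb means exactly 1e6 bp.  Report rounding is decimal half-up (2 decimals for
densities, 1 for percentages) and the unrounded values are always kept
alongside, since table rounding alone can shift a printed figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import IUPAC_AMBIGUITY, round_half_up
from .discovery import ElementRecord, TIRPair


@dataclass
class CompositionSummary:
    n: int
    length_min: int
    length_max: int
    length_mean: float
    length_sd: float
    at_min: float
    at_max: float
    at_mean: float
    at_sd: float


@dataclass
class ConsensusMatrix:
    """Per-position nucleotide frequencies over TIRs of one fixed length."""

    frequencies: pd.DataFrame  # rows: positions, columns: A C G T
    consensus: str
    n_used: int
    n_excluded: int


def density_table(
    element_counts: Mapping[str, int], genome_sizes_mb: Mapping[str, float]
) -> pd.DataFrame:
    """Element density per chromosome plus a total row.

    ``element_counts`` maps chromosome id -> element count; every counted
    chromosome must appear in ``genome_sizes_mb`` (sizes in Mb).  Densities
    are elements per Mb; the ``density`` column is rounded half-up to 2
    decimals and ``density_raw`` keeps the unrounded value.
    """
    unknown = set(element_counts) - set(genome_sizes_mb)
    if unknown:
        raise ValueError(f"element counts on unknown chromosomes: {sorted(unknown)}")
    rows = []
    for chrom, size_mb in genome_sizes_mb.items():
        n = int(element_counts.get(chrom, 0))
        raw = n / size_mb
        rows.append((chrom, size_mb, n, raw, round_half_up(raw, 2)))
    total_mb = sum(genome_sizes_mb.values())
    total_n = sum(int(element_counts.get(c, 0)) for c in genome_sizes_mb)
    raw = total_n / total_mb
    rows.append(("Total", total_mb, total_n, raw, round_half_up(raw, 2)))
    return pd.DataFrame(
        rows, columns=["chrom", "size_mb", "n_elements", "density_raw", "density"]
    )


def density_table_from_catalog(
    elements: Sequence[ElementRecord], genome_sizes_mb: Mapping[str, float]
) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for el in elements:
        counts[el.hit.interval.chrom_id] = counts.get(el.hit.interval.chrom_id, 0) + 1
    return density_table(counts, genome_sizes_mb)


def composition_summary(elements: Sequence[ElementRecord]) -> CompositionSummary:
    """Length and AT-content summary; sd is the sample (n-1) standard deviation."""
    if not elements:
        raise ValueError("composition summary of an empty catalog")
    lengths = np.array([el.length_bp for el in elements], dtype=float)
    ats = np.array([el.at_content for el in elements], dtype=float)
    ddof = 1 if len(elements) > 1 else 0
    return CompositionSummary(
        n=len(elements),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        length_mean=float(lengths.mean()),
        length_sd=float(lengths.std(ddof=ddof)),
        at_min=float(ats.min()),
        at_max=float(ats.max()),
        at_mean=float(ats.mean()),
        at_sd=float(ats.std(ddof=ddof)),
    )


def length_at_correlation(elements: Sequence[ElementRecord]) -> tuple[float, float]:
    """Pearson r between element length and AT-content, with two-sided p.

    p comes from the t transform with n-2 degrees of freedom.  Degenerate
    inputs (n < 3 or zero variance) raise rather than returning NaN.
    """
    if len(elements) < 3:
        raise ValueError("correlation needs at least 3 elements")
    lengths = np.array([el.length_bp for el in elements], dtype=float)
    ats = np.array([el.at_content for el in elements], dtype=float)
    if np.ptp(lengths) == 0 or np.ptp(ats) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r, p = stats.pearsonr(lengths, ats)
    return float(r), float(p)


def tir_consensus(
    tir_pairs: Sequence[TIRPair], length: int = 14
) -> ConsensusMatrix:
    """Position frequency matrix over left TIR arms of the stated length.

    Longer arms are trimmed to their first ``length`` bases (the arm is
    anchored at the element end); shorter arms are excluded and counted.
    N bases are left out of a column's denominator.  The consensus uses
    IUPAC ambiguity codes when multiple bases tie for the column maximum.
    """
    used = [p.left_seq[:length] for p in tir_pairs if p.length >= length]
    n_excluded = len(tir_pairs) - len(used)
    if not used:
        raise ValueError(f"no TIRs of length {length}")
    counts = np.zeros((length, 4), dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for arm in used:
        for pos, base in enumerate(arm):
            if base in base_idx:
                counts[pos, base_idx[base]] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a TIR column contains only N")
    freqs = counts / totals[:, None]
    consensus = []
    for pos in range(length):
        top = freqs[pos].max()
        winners = frozenset(
            b for b, i in base_idx.items() if np.isclose(freqs[pos, i], top)
        )
        consensus.append(IUPAC_AMBIGUITY[winners])
    return ConsensusMatrix(
        frequencies=pd.DataFrame(freqs, columns=["A", "C", "G", "T"]),
        consensus="".join(consensus),
        n_used=len(used),
        n_excluded=n_excluded,
    )


def render_pictogram(matrix: ConsensusMatrix, height: int = 10) -> str:
    """Plain-text pictogram: per position a column of letters scaled by frequency."""
    lines = []
    for pos, row in matrix.frequencies.iterrows():
        parts = [
            f"{base}:{row[base]:.2f}" + "#" * int(round(row[base] * height))
            for base in "ACGT"
            if row[base] > 0
        ]
        lines.append(f"{pos + 1:>3} " + "  ".join(parts))
    return "\n".join(lines) + f"\nconsensus {matrix.consensus}\n"


def chromosome_map(elements: Sequence[ElementRecord]) -> pd.DataFrame:
    """Sorted (chrom, start, end) listing of element positions."""
    rows = [
        (el.hit.interval.chrom_id, el.hit.interval.start, el.hit.interval.end)
        for el in elements
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], ignore_index=True)
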
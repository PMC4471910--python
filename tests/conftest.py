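"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from mitekit.discovery import AlignmentHit, ElementRecord
from mitekit.io_core import GenomeSequence, GenomicInterval
from mitekit import synthetic_data as syn


def make_element(
    chrom="c1", start=0, length=100, at=0.5, strand="+", identity=100.0
) -> ElementRecord:
    """Minimal ElementRecord carrying just the fields a statistic consumes."""
    hit = AlignmentHit(
        interval=GenomicInterval(chrom, start, start + length, strand),
        strand=strand, percent_identity=identity, query_coverage=1.0, score=length,
    )
    return ElementRecord(
        hit=hit, tsd=None, tir=None, complete=True, length_bp=length,
        at_content=at, max_at_run=0,
    )


def brute_force_fold(seq: str, min_loop: int = 3) -> int:
    """Independent maximum-pairing oracle: recursion over the FIRST position
    (pair it with any admissible partner or leave it unpaired), memoized."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        out = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in wc:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1) if seq else 0


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree over labelled taxa plus its exact path-length matrix.

    Returns (labels, matrix, bipartitions) where bipartitions are frozensets
    normalized to the side excluding the first label.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    clusters = [({lab}, {lab: 0.0}) for lab in labels]
    dist = {}

    def join(a, b):
        la = float(rng.uniform(0.05, 0.3))
        lb = float(rng.uniform(0.05, 0.3))
        taxa_a, depth_a = a
        taxa_b, depth_b = b
        for x in taxa_a:
            for y in taxa_b:
                dist[frozenset((x, y))] = depth_a[x] + la + depth_b[y] + lb
        merged_depth = {x: d + la for x, d in depth_a.items()}
        merged_depth.update({y: d + lb for y, d in depth_b.items()})
        return taxa_a | taxa_b, merged_depth

    sides = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        merged = join(a, b)
        if 1 < len(merged[0]) < n_taxa - 1:
            sides.append(frozenset(merged[0]))
        clusters.append(merged)

    ref = labels[0]
    biparts = set()
    for side in sides:
        s = set(side)
        if ref in s:
            s = set(labels) - s
        if 1 < len(s) < n_taxa - 1:
            biparts.add(frozenset(s))
    m = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                m[i, j] = dist[frozenset((x, y))]
    return labels, m, biparts


@pytest.fixture(scope="session")
def small_planting():
    """2 x 100 kb genome with 8 intact + 4 truncated copies, no substitutions."""
    spec = syn.FamilySpec(
        copies_per_chrom=6, substitution_rate=0.0, truncation_probability=0.0
    )
    genomes = syn.generate_genome(n_chrom=2, chrom_len=100_000, seed=11)
    consensus = syn.make_consensus(spec, seed=12)
    intact, truth = syn.plant_elements(
        genomes, spec, seed=13, consensus=consensus
    )
    # re-plant with truncation on a fresh genome for the mixed fixture
    return intact, truth, consensus, spec
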
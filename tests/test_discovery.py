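"""Scanner and structural-validation behaviour, checked against independent
alignment and enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from Bio import Align

from mitekit._util import revcomp
from mitekit.discovery import (
    TIRPair, assemble_element, detect_tir, detect_tsd, fold_max_pairs,
    scan_and_assemble, seed_extend_scan,
)
from mitekit.io_core import GenomeSequence, GenomicInterval
from mitekit import synthetic_data as syn

from conftest import brute_force_fold

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


def _random_seq(rng, n, p_gc=0.4):
    p = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestSeedExtendScan:
    def test_exact_planting_recovered(self):
        rng = np.random.default_rng(0)
        query = _random_seq(rng, 300)
        background = _random_seq(rng, 10_000)
        genome = GenomeSequence("c1", background[:4000] + query + background[4000:])
        hits = seed_extend_scan([genome], query)
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end) == (4000, 4300)
        assert h.percent_identity == 100.0
        assert h.query_coverage == 1.0
        assert h.strand == "+"

    def test_no_shared_kmer_gives_no_hits(self):
        genome = GenomeSequence("c1", "A" * 5000)
        assert seed_extend_scan([genome], "CG" * 50) == []

    def test_query_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            seed_extend_scan([GenomeSequence("c1", "ACGT" * 100)], "ACGTACGT", k=12)

    def test_minus_strand_reported_forward(self):
        rng = np.random.default_rng(1)
        query = _random_seq(rng, 200)
        background = _random_seq(rng, 5000)
        genome = GenomeSequence(
            "c1", background[:2000] + revcomp(query) + background[2000:]
        )
        hits = seed_extend_scan([genome], query)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].interval.start, hits[0].interval.end) == (2000, 2200)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_smith_waterman_oracle(self, seed):
        """On a <=10 kb instance with a 5%-mutated planting, the reported hit
        equals an independent full Smith-Waterman (Biopython) run."""
        rng = np.random.default_rng(seed)
        query = _random_seq(rng, 400)
        mutated = list(query)
        for i in np.flatnonzero(rng.random(len(query)) < 0.05):
            mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
        genome_seq = (
            _random_seq(rng, 3000) + "".join(mutated) + _random_seq(rng, 3000)
        )
        genome = GenomeSequence("c1", genome_seq)
        hits = seed_extend_scan([genome], query)
        assert len(hits) == 1
        hit = hits[0]

        aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-2,
            open_gap_score=-5, extend_gap_score=-1,
        )
        aln = aligner.align(genome_seq, query)[0]
        assert hit.score == int(aln.score)
        tstart = int(aln.aligned[0][0][0])
        tend = int(aln.aligned[0][-1][1])
        assert (hit.interval.start, hit.interval.end) == (tstart, tend)
        counts = aln.counts()
        n_cols = counts.identities + counts.mismatches + counts.gaps
        oracle_identity = 100.0 * counts.identities / n_cols
        assert hit.percent_identity == pytest.approx(oracle_identity, abs=1e-9)

    def test_perfect_thresholds_recover_exactly_planted_set(self, small_planting):
        genomes, truth, consensus, spec = small_planting
        hits = seed_extend_scan(genomes, consensus, min_identity=100, min_coverage=1.0)
        found = {(h.interval.chrom_id, h.interval.start, h.interval.end) for h in hits}
        planted = {
            (c.interval.chrom_id, c.interval.start, c.interval.end)
            for c in truth.copies
        }
        assert found == planted


class TestTsd:
    def test_duplicated_taa(self):
        genome = GenomeSequence("c1", "GGGGGTAA" + "C" * 20 + "TAACCCCC")
        pair = detect_tsd(genome, GenomicInterval("c1", 8, 28))
        assert (pair.left_seq, pair.right_seq) == ("TAA", "TAA")
        assert pair.is_duplicated

    def test_non_duplicated(self):
        genome = GenomeSequence("c1", "GGTAC" + "G" * 20 + "TAACC")
        pair = detect_tsd(genome, GenomicInterval("c1", 5, 25))
        assert (pair.left_seq, pair.right_seq) == ("TAC", "TAA")
        assert not pair.is_duplicated

    def test_n_blocks_duplication(self):
        genome = GenomeSequence("c1", "GGTNA" + "G" * 20 + "TNACC")
        assert not detect_tsd(genome, GenomicInterval("c1", 5, 25)).is_duplicated

    def test_short_flank_rejected(self):
        genome = GenomeSequence("c1", "AC" + "G" * 20 + "ACGT")
        with pytest.raises(ValueError):
            detect_tsd(genome, GenomicInterval("c1", 2, 22))

    def test_all_planted_insertions_called_duplicated(self, small_planting):
        genomes, truth, consensus, spec = small_planting
        by_chrom = {g.chrom_id: g for g in genomes}
        for copy in truth.copies:
            pair = detect_tsd(by_chrom[copy.interval.chrom_id], copy.interval)
            assert pair.is_duplicated
            assert pair.left_seq == copy.tsd


TIR = "GGGTCTGACTGGTT"


def brute_force_tir(seq, min_len=10, max_len=20, max_mismatch=4):
    """Exhaustive oracle over all arm lengths: best (n_paired, -n_mismatch)."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    best = None
    for L in range(min_len, max_len + 1):
        if 2 * L > len(seq):
            continue
        left, right = seq[:L], seq[-L:]
        paired = sum((a, b) in wc for a, b in zip(left, right[::-1]))
        if L - paired > max_mismatch:
            continue
        key = (paired, -(L - paired))
        if best is None or key > best[0]:
            best = (key, L, paired)
    return best


class TestTir:
    def test_perfect_consensus_tir(self):
        # core ends with non-pairing A...A boundary so L=14 is the optimum
        elem = TIR + "A" * 30 + revcomp(TIR)
        tir = detect_tir(elem)
        assert tir is not None
        assert tir.length == 14
        assert tir.n_paired == 14
        assert tir.n_mismatch == 0

    def test_poly_a_has_no_tir(self):
        assert detect_tir("A" * 60) is None

    def test_engineered_mismatches_match_oracle(self):
        left = "GGGTCTGACTGGTT"
        right = list(revcomp(left))
        for pos in (1, 4, 8, 12):  # 4 engineered mismatches
            right[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[pos]]
        elem = left + "A" * 30 + "".join(right)
        tir = detect_tir(elem)
        oracle = brute_force_tir(elem)
        assert tir.n_paired == 10
        assert tir.length == 14
        assert (tir.n_paired, -tir.n_mismatch) == oracle[0]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_random_elements(self, seed):
        rng = np.random.default_rng(seed)
        elem = _random_seq(rng, int(rng.integers(40, 120)))
        tir = detect_tir(elem)
        oracle = brute_force_tir(elem)
        if oracle is None:
            assert tir is None
        else:
            assert (tir.n_paired, -tir.n_mismatch) == oracle[0]

    @given(core=st.text(alphabet="ACGT", min_size=12, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_revcomp_symmetry(self, core):
        elem = TIR + core + revcomp(TIR)
        fwd = detect_tir(elem)
        rev = detect_tir(revcomp(elem))
        assert (fwd is None) == (rev is None)
        if fwd is not None:
            assert fwd.length == rev.length
            assert fwd.n_paired == rev.n_paired


class TestFold:
    def test_perfect_stem(self):
        fold = fold_max_pairs("GGGAAACCC", min_loop=3)
        assert fold.n_pairs == 3
        assert fold.structure == "(((...)))"

    @pytest.mark.parametrize("seq", ["", "A", "ACGT"])
    def test_too_short_to_pair(self, seq):
        assert fold_max_pairs(seq).n_pairs == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle_up_to_length_12(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, int(rng.integers(4, 13)), p_gc=0.5)
        fold = fold_max_pairs(seq)
        assert fold.n_pairs == brute_force_fold(seq)
        # structure is consistent with the count and the loop constraint
        assert len(fold.pairs) == fold.n_pairs
        assert all(j - i - 1 >= 3 for i, j in fold.pairs)

    @given(seq=dna.filter(lambda s: len(s) >= 6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_revcomp_invariance(self, seq):
        assert fold_max_pairs(seq).n_pairs == fold_max_pairs(revcomp(seq)).n_pairs

    def test_n_never_pairs(self):
        assert fold_max_pairs("GGGAAANNN").n_pairs == 0


class TestAssemble:
    def test_planted_elements_complete(self, small_planting):
        genomes, truth, consensus, spec = small_planting
        elements = scan_and_assemble(genomes, consensus)
        assert len(elements) == len(truth.copies)
        assert all(e.complete for e in elements)
        by_pos = {
            (c.interval.chrom_id, c.interval.start): c for c in truth.copies
        }
        for e in elements:
            key = (e.hit.interval.chrom_id, e.hit.interval.start)
            assert key in by_pos
            copy = by_pos[key]
            assert e.hit.interval.end == copy.interval.end
            assert e.tsd.left_seq == copy.tsd

    def test_truncated_copies_called_partial(self):
        spec = syn.FamilySpec(
            copies_per_chrom=10, substitution_rate=0.0, truncation_probability=1.0
        )
        genomes = syn.generate_genome(n_chrom=1, chrom_len=100_000, seed=21)
        genomes, truth = syn.plant_elements(genomes, spec, seed=22)
        elements = scan_and_assemble(genomes, truth.consensus)
        assert len(elements) == len(truth.copies)
        assert not any(e.complete for e in elements)

    def test_mixed_completeness_recovered_exactly(self):
        """Intact copies are called complete and truncated ones partial, with
        no crossover, on a genome carrying both."""
        spec_full = syn.FamilySpec(copies_per_chrom=6, substitution_rate=0.0)
        consensus = syn.make_consensus(spec_full, seed=30)
        chr_a = syn.generate_genome(n_chrom=1, chrom_len=100_000, seed=31, prefix="a")
        chr_b = syn.generate_genome(n_chrom=1, chrom_len=80_000, seed=34, prefix="b")
        chr_a, truth_full = syn.plant_elements(
            chr_a, spec_full, seed=32, consensus=consensus
        )
        spec_trunc = syn.FamilySpec(
            copies_per_chrom=4, substitution_rate=0.0, truncation_probability=1.0
        )
        chr_b, truth_trunc = syn.plant_elements(
            chr_b, spec_trunc, seed=33, consensus=consensus
        )
        genomes = chr_a + chr_b
        elements = scan_and_assemble(genomes, consensus)
        assert len(elements) == 10
        complete_chroms = [
            e.hit.interval.chrom_id for e in elements if e.complete
        ]
        partial_chroms = [
            e.hit.interval.chrom_id for e in elements if not e.complete
        ]
        assert complete_chroms == ["a1"] * 6
        assert partial_chroms == ["b1"] * 4

    def test_ablated_flank_yields_partial(self):
        spec = syn.FamilySpec(copies_per_chrom=1, substitution_rate=0.0)
        genomes = syn.generate_genome(n_chrom=1, chrom_len=30_000, seed=41)
        genomes, truth = syn.plant_elements(
            genomes, spec, seed=42, min_spacing=100, margin=2000
        )
        copy = truth.copies[0]
        g = genomes[0]
        # destroy the right TSD copy
        s = g.sequence
        broken = s[: copy.interval.end] + "GGG" + s[copy.interval.end + 3 :]
        hits = seed_extend_scan([GenomeSequence("chr1", broken)], truth.consensus)
        assert len(hits) == 1
        rec = assemble_element(GenomeSequence("chr1", broken), hits[0])
        assert not rec.complete

    def test_complete_implies_structure_invariant(self, small_planting):
        genomes, truth, consensus, spec = small_planting
        for e in scan_and_assemble(genomes, consensus):
            if e.complete:
                assert e.tsd is not None and e.tsd.is_duplicated
                assert e.tir is not None and e.tir.n_mismatch <= 4
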
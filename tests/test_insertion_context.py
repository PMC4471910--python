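"""Context classification, summaries, UTR distances, transcript fragments and
locus genotyping."""

import numpy as np
import pytest

from mitekit import synthetic_data as syn
from mitekit.insertion_context import (
    CATEGORIES, classify_context, genotype_locus, locate_fragment_in_transcript,
    summarize_contexts, summarize_counts, utr_distance,
)
from mitekit.io_core import GeneModel, GenomeSequence, GenomicInterval


def _gene(chrom="c1", start=10_000, end=12_000, strand="+", exons=None,
          utr5=None, utr3=None, gene_id="g1"):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(
        gene_id, iv,
        exons=exons or [GenomicInterval(chrom, start, end, strand)],
        five_prime_utrs=utr5 or [],
        three_prime_utrs=utr3 or [],
    )


class TestClassify:
    def test_element_in_intron(self):
        gene = _gene(
            exons=[
                GenomicInterval("c1", 10_000, 10_500, "+"),
                GenomicInterval("c1", 11_500, 12_000, "+"),
            ]
        )
        elem = GenomicInterval("c1", 10_800, 11_300)
        ctx = classify_context(elem, [gene])
        assert (ctx.category, ctx.distance_bp, ctx.sub_feature) == ("gene", 0, "intron")

    def test_five_flank_500bp_before_plus_gene(self):
        gene = _gene()
        elem = GenomicInterval("c1", 9_000, 9_500)
        ctx = classify_context(elem, [gene])
        assert ctx.category == "five_flank_lt1k"
        assert ctx.distance_bp == 500
        assert ctx.nearest_gene_id == "g1"

    def test_beyond_3kb_is_intergenic(self):
        gene = _gene()
        ctx = classify_context(GenomicInterval("c1", 5_000, 6_500), [gene])
        assert ctx.category == "intergenic"
        assert ctx.distance_bp == 3_500

    def test_no_gene_on_chromosome_is_intergenic(self):
        ctx = classify_context(GenomicInterval("c9", 100, 200), [_gene()])
        assert ctx.category == "intergenic"
        assert ctx.nearest_gene_id is None

    def test_bin_boundaries_half_open(self):
        gene = _gene()
        for gap, cat in [
            (999, "five_flank_lt1k"), (1000, "five_flank_1to2k"),
            (1999, "five_flank_1to2k"), (2000, "five_flank_2to3k"),
            (2999, "five_flank_2to3k"), (3000, "intergenic"),
        ]:
            elem = GenomicInterval("c1", 10_000 - gap - 100, 10_000 - gap)
            assert classify_context(elem, [gene]).category == cat, gap

    def test_strand_mirror_swaps_flanks(self):
        elem = GenomicInterval("c1", 9_000, 9_500)
        plus = classify_context(elem, [_gene(strand="+")])
        minus = classify_context(elem, [_gene(strand="-")])
        assert plus.category == "five_flank_lt1k"
        assert minus.category == "three_flank_lt1k"
        assert plus.distance_bp == minus.distance_bp

    def test_increasing_distance_never_moves_nearer_bin(self):
        gene = _gene()
        order = {c: i for i, c in enumerate(CATEGORIES[1:4] + ["intergenic"])}
        last = -1
        for gap in range(100, 4000, 100):
            elem = GenomicInterval("c1", 10_000 - gap - 50, 10_000 - gap)
            cat = classify_context(elem, [gene]).category
            assert order[cat] >= last
            last = order[cat]

    def test_nearest_gene_wins(self):
        near = _gene(start=10_000, end=12_000, gene_id="near")
        far = _gene(start=20_000, end=22_000, gene_id="far")
        ctx = classify_context(GenomicInterval("c1", 9_000, 9_500), [far, near])
        assert ctx.nearest_gene_id == "near"

    def test_planted_plan_recovered(self):
        spec = syn.FamilySpec(copies_per_chrom=10, substitution_rate=0.0)
        genomes = syn.generate_genome(n_chrom=2, chrom_len=110_000, seed=51)
        genomes, truth = syn.plant_elements(genomes, spec, seed=52)
        counts = {
            "gene": 3, "five_flank_lt1k": 3, "five_flank_1to2k": 2,
            "five_flank_2to3k": 2, "three_flank_lt1k": 3,
            "three_flank_1to2k": 2, "three_flank_2to3k": 2, "intergenic": 3,
        }
        plan = syn.draw_context_plan(20, counts, seed=53)
        genes = syn.generate_annotation(genomes, truth, plan, seed=54)
        observed = {cat: 0 for cat in CATEGORIES}
        for copy in truth.copies:
            ctx = classify_context(copy.interval, genes)
            assert ctx.category == copy.planned_category
            observed[ctx.category] += 1
        assert observed == counts


class TestSummaries:
    BRAPA = {
        "gene": 24, "five_flank_lt1k": 110, "five_flank_1to2k": 66,
        "five_flank_2to3k": 33, "three_flank_lt1k": 70,
        "three_flank_1to2k": 52, "three_flank_2to3k": 20, "intergenic": 129,
    }
    ATHAL = {
        "gene": 2, "five_flank_lt1k": 18, "five_flank_1to2k": 2,
        "five_flank_2to3k": 1, "three_flank_lt1k": 8, "three_flank_1to2k": 4,
        "three_flank_2to3k": 0, "intergenic": 3,
    }

    def test_brapa_published_aggregates(self):
        s = summarize_counts(self.BRAPA)
        assert s.n_total == 504
        assert s.gene_rich_percent == 74.4
        assert s.percentages["gene"] == 4.8
        assert s.percentages["five_flank_lt1k"] == 21.8

    def test_athaliana_published_aggregates(self):
        s = summarize_counts(self.ATHAL)
        assert s.n_total == 38
        assert s.gene_rich_percent == 92.1
        assert s.percentages["intergenic"] == 7.9
        lt1k = s.counts["five_flank_lt1k"] + s.counts["three_flank_lt1k"]
        assert lt1k == 26

    def test_single_category_is_100_percent(self):
        s = summarize_counts({"gene": 1})
        assert s.percentages["gene"] == 100.0

    def test_counts_partition(self):
        s = summarize_counts(self.BRAPA)
        assert sum(s.counts.values()) == s.n_total
        assert abs(sum(s.percentages.values()) - 100.0) <= 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_contexts([])


class TestUtrDistance:
    def test_inside_three_utr(self):
        gene = _gene(utr3=[GenomicInterval("c1", 11_800, 12_000, "+")])
        assert utr_distance(GenomicInterval("c1", 11_850, 11_950), [gene]) == (0, True)

    def test_distance_to_nearest_utr(self):
        gene = _gene(utr5=[GenomicInterval("c1", 10_000, 10_150, "+")])
        assert utr_distance(GenomicInterval("c1", 9_100, 9_600), [gene]) == (400, False)

    def test_no_utr_annotation_gives_none(self):
        assert utr_distance(GenomicInterval("c1", 9_000, 9_500), [_gene()]) is None

    def test_planted_utr_proximity_counts_recovered(self):
        """A panel planted with a known number of <500 bp UTR distances
        reproduces that count."""
        spec = syn.FamilySpec(copies_per_chrom=8, substitution_rate=0.0)
        genomes = syn.generate_genome(n_chrom=1, chrom_len=90_000, seed=61)
        genomes, truth = syn.plant_elements(genomes, spec, seed=62)
        counts = {"five_flank_lt1k": 4, "five_flank_1to2k": 2, "intergenic": 2}
        plan = syn.draw_context_plan(8, counts, seed=63)
        genes = syn.generate_annotation(genomes, truth, plan, seed=64)
        n_close = 0
        for copy in truth.copies:
            res = utr_distance(copy.interval, genes)
            if res is not None and res[0] < 500:
                n_close += 1
        expected = sum(
            1 for c in truth.copies
            if c.planned_category == "five_flank_lt1k" and c.planned_distance < 500
        )
        assert n_close == expected


@pytest.fixture(scope="module")
def utr_scene():
    spec = syn.FamilySpec(copies_per_chrom=2, substitution_rate=0.0)
    genomes = syn.generate_genome(n_chrom=1, chrom_len=40_000, seed=71)
    consensus = syn.make_consensus(spec, seed=70)
    genomes, truth = syn.plant_elements(
        genomes, spec, seed=72, consensus=consensus,
        min_spacing=15_000, margin=6_000,
    )
    plan = [
        syn.ContextPlan("gene", 0, "three_utr"),
        syn.ContextPlan("gene", 0, "intron"),
    ]
    genes = syn.generate_annotation(genomes, truth, plan, seed=73)
    return genomes, truth, genes, consensus


class TestFragmentLocalization:
    def test_three_utr_fragment(self, utr_scene):
        genomes, truth, genes, consensus = utr_scene
        tx = syn.generate_transcripts(genomes, genes)
        label = locate_fragment_in_transcript(
            dict(tx)[f"{genes[0].gene_id}.t1"], consensus, genes[0], genomes[0]
        )
        assert label == "three_utr"

    def test_intron_retention_fragment(self, utr_scene):
        genomes, truth, genes, consensus = utr_scene
        tx = syn.generate_transcripts(
            genomes, genes, retain_introns=[genes[1].gene_id]
        )
        label = locate_fragment_in_transcript(
            dict(tx)[f"{genes[1].gene_id}.t1"], consensus, genes[1], genomes[0]
        )
        assert label == "intron"

    def test_fragment_free_transcript_unplaced(self, utr_scene):
        genomes, truth, genes, consensus = utr_scene
        rng = np.random.default_rng(5)
        est = "".join(rng.choice(list("ACGT"), size=300))
        assert (
            locate_fragment_in_transcript(est, consensus, genes[0], genomes[0])
            == "unplaced"
        )


class TestGenotyping:
    def test_species_specific_pattern(self):
        spec = syn.FamilySpec()
        consensus = syn.make_consensus(spec, seed=81)
        pattern = {"rapa": True, "napus": False, "oleracea": False}
        genomes, la, ra = syn.generate_polymorphism_panel(
            consensus, pattern, seed=82
        )
        gt = genotype_locus(genomes, la, ra, consensus)
        assert gt.calls == {"rapa": "present", "napus": "absent",
                            "oleracea": "absent"}
        assert (
            gt.product_sizes["rapa"] - gt.product_sizes["napus"]
            == len(consensus) + 3
        )

    def test_all_present(self):
        consensus = syn.make_consensus(syn.FamilySpec(), seed=83)
        genomes, la, ra = syn.generate_polymorphism_panel(
            consensus, {"a": True, "b": True}, seed=84
        )
        gt = genotype_locus(genomes, la, ra, consensus)
        assert set(gt.calls.values()) == {"present"}

    def test_missing_anchor_gives_no_data(self):
        consensus = syn.make_consensus(syn.FamilySpec(), seed=85)
        genomes, la, ra = syn.generate_polymorphism_panel(
            consensus, {"a": True}, seed=86
        )
        unrelated = GenomeSequence("other", "ACGT" * 300)
        gt = genotype_locus(genomes + [unrelated], la, ra, consensus)
        assert gt.calls["a"] == "present"
        assert gt.calls["other"] == "no_data"

    def test_short_anchor_rejected(self):
        consensus = syn.make_consensus(syn.FamilySpec(), seed=87)
        with pytest.raises(ValueError):
            genotype_locus([GenomeSequence("a", "ACGT" * 100)], "ACGTACGT",
                           "A" * 20, consensus)

    def test_locus_on_reverse_strand_genome(self):
        from mitekit._util import revcomp

        consensus = syn.make_consensus(syn.FamilySpec(), seed=88)
        genomes, la, ra = syn.generate_polymorphism_panel(
            consensus, {"a": True}, seed=89
        )
        flipped = GenomeSequence("flipped", revcomp(genomes[0].sequence))
        gt = genotype_locus([flipped], la, ra, consensus)
        assert gt.calls["flipped"] == "present"
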
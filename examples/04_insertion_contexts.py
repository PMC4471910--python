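"""Classify element insertions relative to genes and summarize the bins.

Plants copies with a known plan of insertion contexts (gene body, 5'/3'
flank distance bins, intergenic), builds the matching annotation, and shows
the classifier reproducing the plan.
"""

from mitekit import synthetic_data as syn
from mitekit.insertion_context import classify_context, summarize_contexts

spec = syn.FamilySpec(copies_per_chrom=10, substitution_rate=0.0)
genomes = syn.generate_genome(n_chrom=2, chrom_len=110_000, seed=5)
genomes, truth = syn.plant_elements(genomes, spec, seed=6)

counts = {
    "gene": 2, "five_flank_lt1k": 4, "five_flank_1to2k": 3,
    "five_flank_2to3k": 1, "three_flank_lt1k": 3, "three_flank_1to2k": 2,
    "three_flank_2to3k": 1, "intergenic": 4,
}
plan = syn.draw_context_plan(20, counts, seed=7)
genes = syn.generate_annotation(genomes, truth, plan, seed=8)

contexts = [classify_context(c.interval, genes) for c in truth.copies]
summary = summarize_contexts(contexts)

print("category             count  percent")
for cat, n in summary.counts.items():
    print(f"{cat:20} {n:5}  {summary.percentages[cat]:6.1f}")
print(f"\ngene-rich (gene body or <3 kb from a gene): {summary.gene_rich_percent}%")
n_ok = sum(
    ctx.category == c.planned_category for ctx, c in zip(contexts, truth.copies)
)
print(f"planned category recovered for {n_ok}/{len(contexts)} copies")
print(
    "\nThe gene-rich aggregate is the figure MITE studies quote to show"
    "\ninsertions cluster near genes rather than in deep intergenic space."
)
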
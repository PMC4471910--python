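"""Match a small RNA to an element interior and test the precursor fold.

Plants a 24-nt small RNA at element positions 499-522 inside a region that
can fold back on itself, finds the match, and assesses whether the matched
neighborhood forms a miRNA-precursor-like stem-loop.
"""

import numpy as np

from mitekit._util import revcomp
from mitekit.smallrna import assess_precursor, find_matches, match_transcripts

rng = np.random.default_rng(40)
mirna = "UUGACGGUCAAUUAGCCAGUCAAA"  # RNA-space query, 24 nt
mature = mirna.replace("U", "T")
arm = mature + "".join(rng.choice(list("ACGT"), size=20))
hairpin = arm + "TCTTCGAA" + revcomp(arm)
element = (
    "".join(rng.choice(list("ACGT"), size=498)) + hairpin
    + "".join(rng.choice(list("ACGT"), size=60))
)

matches = [m for m in find_matches(element, mirna, max_mismatch=0)
           if m.strand == "+"]
m = matches[0]
print(f"match: element positions {m.start}-{m.end} "
      f"({m.length} nt, {m.n_mismatch} mismatches, strand {m.strand})")

assessment = assess_precursor(element, m, window=len(hairpin), min_pairs=16)
print(f"precursor window {assessment.window_start}-{assessment.window_end}: "
      f"{assessment.fold.n_pairs} base pairs, passes={assessment.passes}")

transcripts = [
    (f"est{i}", "".join(rng.choice(list("ACGT"), size=150)) + mature
     + "".join(rng.choice(list("ACGT"), size=50)))
    for i in range(5)
] + [("bg", "".join(rng.choice(list("ACGT"), size=220)))]
_, n_perfect = match_transcripts(transcripts, mirna)
print(f"transcripts with a perfect match: {n_perfect}/{len(transcripts)}")
print(
    "\nThe mature small RNA sits on one arm of a stem-loop that folds with"
    "\nenough base pairs to look like a miRNA precursor, and expressed"
    "\nsequences carrying the element fragment are detected as targets."
)
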
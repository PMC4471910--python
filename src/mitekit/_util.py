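"""Small sequence and numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson-Crick pairs over DNA letters; N never pairs with anything.
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

IUPAC_AMBIGUITY = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def pairs_wc(a: str, b: str) -> bool:
    """True if bases a and b form a Watson-Crick pair. N pairs with nothing."""
    return (a, b) in WC_PAIRS


def at_content(seq: str) -> float:
    """A+T fraction over non-N bases. Raises on a sequence of only N."""
    n_at = seq.count("A") + seq.count("T")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("AT-content undefined: no non-N bases")
    return n_at / denom


def max_at_run(seq: str) -> int:
    """Length of the longest contiguous run of A/T bases."""
    best = run = 0
    for base in seq:
        if base in "AT":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 digits), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_dna(seq: str, map_invalid_to_n: bool = False) -> str:
    """Uppercase and validate a DNA string over {A,C,G,T,N}.

    U (RNA input) is mapped to T.  Other characters either raise or are
    mapped to N depending on ``map_invalid_to_n``.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        if not map_invalid_to_n:
            raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
        s = "".join(c if c in "ACGTN" else "N" for c in s)
    return s
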
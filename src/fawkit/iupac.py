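"""IUPAC nucleotide code helpers shared by the typing and simulation modules.

Sanger sequencing of a diploid (or hemizygous-duplicated) template collapses a
heterozygous site into a single ambiguity code, so merging and detecting these
codes is a first-class operation here rather than an edge case.
"""

from __future__ import annotations

from Bio.Seq import Seq

#: base-set interpretation of every IUPAC nucleotide code
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: inverse map from a frozenset of concrete bases to its IUPAC code
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


def is_dna(seq: str) -> bool:
    """True if every character of *seq* is an IUPAC nucleotide code."""
    return len(seq) > 0 and set(seq.upper()) <= set(IUPAC_SETS)


def has_ambiguity(seq: str) -> bool:
    """True if *seq* contains at least one ambiguity code (R,Y,S,W,K,M,B,D,H,V,N)."""
    return any(c in AMBIGUITY_CODES for c in seq.upper())


def merge_bases(a: str, b: str) -> str:
    """IUPAC code covering the union of the base sets of *a* and *b*.

    merge_bases('A', 'G') == 'R'; merging a base with itself returns it.
    """
    union = IUPAC_SETS[a.upper()] | IUPAC_SETS[b.upper()]
    return SETS_TO_CODE[union]


def merge_sequences(a: str, b: str) -> str:
    """Position-wise IUPAC merge of two equal-length sequences.

    Models the consensus read of a heterozygote whose two alleles are *a* and
    *b*: identical positions stay unambiguous, differing positions collapse to
    the 2-base (or wider) ambiguity code.
    """
    if len(a) != len(b):
        raise ValueError("merge_sequences requires equal-length inputs")
    return "".join(merge_bases(x, y) for x, y in zip(a, b))


def revcomp(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement()).upper()


def bases_compatible(a: str, b: str) -> bool:
    """True if the base sets of the two codes intersect (e.g. 'R' matches 'A')."""
    return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])
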
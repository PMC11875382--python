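"""Synthetic reference amplicons, marker definitions, and haplotype library.

No reference accessions are shipped with the assays this package implements,
so the reference COI and Tpi amplicons here are synthetic: random backbones
with the published primer sites embedded at the ends and the polymorphic
marker sites placed at known offsets, each bracketed by unique 15-mer flanks.
Real GenBank sequences can be dropped in by building a ``MarkerConfig`` with
flanks read from them; nothing downstream depends on these particular
backbones.

The published assay coordinates (mCOI1164D / mCOI1287R; gTpi165Y / gTpi168Y /
gTpi183Y) are primer-relative labels, and the 165/168 sites sit 3 bp apart —
too close for independent 15-bp locator flanks once both are polymorphic.
The synthetic exon therefore spaces the three sites >= 20 bp apart while
keeping the assay names; sites are always located by flank match, never by
coordinate.

The TpiI4a200 haplotype library holds 13 C-strain intron variants under the
field's haplotype nomenclature (AfrCa1a/AfrCa1c/AfrCa2b/AfrCa2c, w01...) plus
a small diverged R-strain clade for phylogenetic strain grouping.  All
sequences are synthetic stand-ins generated deterministically at import.
"""

from __future__ import annotations

import numpy as np

from .iupac import revcomp
from .markers import MarkerConfig, MarkerSiteSpec, ReferenceHaplotypeSet

__all__ = [
    "C891F",
    "C1472R",
    "T412F",
    "T1140R",
    "COI_BACKBONE",
    "COI_SITE_OFFSETS",
    "TPI_BACKBONE",
    "TPI_EXON_SITE_OFFSETS",
    "TPI_INTRON_SPAN",
    "CONSENSUS_INTRON",
    "TPI_HAPLOTYPE_LIBRARY",
    "TPI_REFERENCE_SET",
    "DEFAULT_MARKER_CONFIG",
    "coi_amplicon",
    "tpi_amplicon",
    "tpiI4a200_segment_of",
]

# published primer pairs for the two assays
C891F = "TACACGAGCATATTTTACATC"
C1472R = "GCTGGTGGTAAATTTTGATATC"
T412F = "CCGGACTGAAGGTTATCGCTTG"
T1140R = "GCGGAAGCATTCGCTGACAACC"

_FLANK_K = 15
_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _unique_in(seq: str, kmer: str) -> bool:
    return seq.count(kmer) == 1 and revcomp(seq).count(kmer) == 0


def _flanks(seq: str, pos: int) -> tuple[str, str]:
    return seq[pos - _FLANK_K : pos], seq[pos + 1 : pos + 1 + _FLANK_K]


def _build_coi_backbone() -> tuple[str, dict]:
    """COIB amplicon backbone with CSh1 (A/A) alleles at the two marker sites.

    Site offsets 273 and 396 from the forward-primer start mirror the
    primer-relative spacing of the published assay names (1164-891, 1287-891).
    """
    offsets = {"mCOI1164D": 273, "mCOI1287R": 396}
    for attempt in range(100):
        rng = np.random.default_rng(20240308 + attempt)
        body = _random_dna(rng, 559)
        seq = C891F + body + revcomp(C1472R)
        seq = "".join(
            "A" if i in offsets.values() else c for i, c in enumerate(seq)
        )
        kmers = [C891F, revcomp(C1472R)]
        for pos in offsets.values():
            kmers.extend(_flanks(seq, pos))
        # flanks must stay unique under every allele substitution at the sites
        probes = [seq]
        for pos in offsets.values():
            for b in "CGT":
                probes.append(seq[:pos] + b + seq[pos + 1 :])
        if all(_unique_in(p, k) for p in probes for k in kmers):
            return seq, offsets
    raise RuntimeError("could not build a COI backbone with unique flanks")


def _build_tpi_backbone() -> tuple[str, dict, tuple]:
    """Tpi amplicon backbone: exon 4 (C-strain alleles), intron 4, exon 5 start.

    Layout: t412F .. exon4 with the three strain SNP sites (C alleles) ..
    GT-intron-AG (335 bp) .. exon5 anchor .. t1140R reverse complement.
    """
    exon_sites = {"gTpi165Y": 60, "gTpi168Y": 85, "gTpi183Y": 110}
    intron_start, intron_end = 160, 495  # intron length 335
    for attempt in range(100):
        rng = np.random.default_rng(19850412 + attempt)
        seq = list(T412F + _random_dna(rng, 520) + revcomp(T1140R))
        for pos in exon_sites.values():
            seq[pos] = "C"
        seq[intron_start], seq[intron_start + 1] = "G", "T"
        seq[intron_end - 2], seq[intron_end - 1] = "A", "G"
        s = "".join(seq)
        kmers = [T412F, revcomp(T1140R)]
        for pos in exon_sites.values():
            kmers.extend(_flanks(s, pos))
        exon4_end_flank = s[intron_start - _FLANK_K : intron_start]
        exon5_anchor = s[intron_end : intron_end + _FLANK_K]
        kmers.extend([exon4_end_flank, exon5_anchor])
        probes = [s]
        for pos in exon_sites.values():
            for b in "AGT":
                probes.append(s[:pos] + b + s[pos + 1 :])
        if all(_unique_in(p, k) for p in probes for k in kmers):
            return s, exon_sites, (intron_start, intron_end)
    raise RuntimeError("could not build a Tpi backbone with unique flanks")


COI_BACKBONE, COI_SITE_OFFSETS = _build_coi_backbone()
TPI_BACKBONE, TPI_EXON_SITE_OFFSETS, TPI_INTRON_SPAN = _build_tpi_backbone()

#: consensus TpiI4 intron (GT...AG, 335 bp) carried by the backbone
CONSENSUS_INTRON = TPI_BACKBONE[TPI_INTRON_SPAN[0] : TPI_INTRON_SPAN[1]]


def _build_haplotype_library() -> ReferenceHaplotypeSet:
    """13 C-strain intron variants plus a diverged 4-member R-strain clade.

    Substitutions are confined to the first 60% of the intron so every pair of
    haplotypes is distinguishable within the TpiI4a200 window; w10 instead
    carries a 3-bp deletion, exercising the length-variant path.  R-strain
    intron variants carry ~15 clustered substitutions, giving the clear
    two-clade structure the strain-grouping phylogeny relies on.
    """
    rng = np.random.default_rng(173)
    seg_len = int(0.6 * len(CONSENSUS_INTRON))  # 201
    editable = np.arange(4, seg_len - 4)  # keep GT donor + margins intact

    c_labels = [
        "AfrCa1a", "AfrCa1b", "AfrCa1c", "AfrCa2a", "AfrCa2b", "AfrCa2c",
        "w01", "w05", "w07", "w08", "w12", "ic04",
    ]
    entries: list[tuple] = []
    seen_segments: set[str] = set()

    def add(label: str, intron: str, strain: str) -> None:
        seg = intron[: int(0.6 * len(intron))]
        if seg in seen_segments:
            raise RuntimeError(f"haplotype {label} segment collides with another")
        seen_segments.add(seg)
        entries.append((label, intron, strain))

    add("AfrCa1a", CONSENSUS_INTRON, "C")  # consensus itself is a haplotype
    for i, label in enumerate(c_labels[1:], start=1):
        n_sub = 1 + i % 4
        intron = list(CONSENSUS_INTRON)
        pos = rng.choice(editable, size=n_sub, replace=False)
        for p in pos:
            old = intron[p]
            intron[p] = rng.choice([b for b in "ACGT" if b != old])
        add(label, "".join(intron), "C")
    # w10: 3-bp deletion inside the segment window (length-variant haplotype)
    add("w10", CONSENSUS_INTRON[:100] + CONSENSUS_INTRON[103:], "C")

    # R-strain clade: shared block of 12 substitutions + 3 private ones each
    shared = rng.choice(editable, size=12, replace=False)
    for j in range(4):
        intron = list(CONSENSUS_INTRON)
        for p in shared:
            old = intron[p]
            intron[p] = "ACGT"[(("ACGT".index(old)) + 1) % 4]
        private = rng.choice(editable, size=3, replace=False)
        for p in private:
            old = intron[p]
            intron[p] = rng.choice([b for b in "ACGT" if b != old])
        add(f"Rs0{j + 1}", "".join(intron), "R")

    return ReferenceHaplotypeSet(
        entries=tuple(entries),
        provenance="synthetic stand-in library (deterministic, seed 173)",
    )


TPI_HAPLOTYPE_LIBRARY = _build_haplotype_library()

#: reference set over TpiI4a200 *segments* (what phylogenetic grouping compares)
TPI_REFERENCE_SET = ReferenceHaplotypeSet(
    entries=tuple(
        (label, intron[: int(0.6 * len(intron))], strain)
        for label, intron, strain in TPI_HAPLOTYPE_LIBRARY.entries
    ),
    provenance=TPI_HAPLOTYPE_LIBRARY.provenance,
)


def _site_spec(gene: str, name: str, backbone: str, pos: int) -> MarkerSiteSpec:
    left, right = _flanks(backbone, pos)
    return MarkerSiteSpec(gene=gene, site_name=name, left_flank=left, right_flank=right)


DEFAULT_MARKER_CONFIG = MarkerConfig(
    coib_fwd=C891F,
    coib_rev=C1472R,
    tpi_fwd=T412F,
    tpi_rev=T1140R,
    sites={
        "mCOI1164D": _site_spec("COI", "mCOI1164D", COI_BACKBONE, COI_SITE_OFFSETS["mCOI1164D"]),
        "mCOI1287R": _site_spec("COI", "mCOI1287R", COI_BACKBONE, COI_SITE_OFFSETS["mCOI1287R"]),
        "gTpi165Y": _site_spec("Tpi", "gTpi165Y", TPI_BACKBONE, TPI_EXON_SITE_OFFSETS["gTpi165Y"]),
        "gTpi168Y": _site_spec("Tpi", "gTpi168Y", TPI_BACKBONE, TPI_EXON_SITE_OFFSETS["gTpi168Y"]),
        "gTpi183Y": _site_spec("Tpi", "gTpi183Y", TPI_BACKBONE, TPI_EXON_SITE_OFFSETS["gTpi183Y"]),
    },
    exon4_end_flank=TPI_BACKBONE[TPI_INTRON_SPAN[0] - _FLANK_K : TPI_INTRON_SPAN[0]],
    exon5_anchor=TPI_BACKBONE[TPI_INTRON_SPAN[1] : TPI_INTRON_SPAN[1] + _FLANK_K],
    tpi_strain_map={"C": "C", "T": "R"},
)


def coi_amplicon(allele_1164: str, allele_1287: str) -> str:
    """COIB amplicon carrying the given alleles at the two marker sites."""
    seq = list(COI_BACKBONE)
    seq[COI_SITE_OFFSETS["mCOI1164D"]] = allele_1164.upper()
    seq[COI_SITE_OFFSETS["mCOI1287R"]] = allele_1287.upper()
    return "".join(seq)


def tpi_amplicon(intron: str, strain: str) -> str:
    """Tpi amplicon with the given intron sequence and strain exon alleles.

    C-strain exons carry C at all three SNP sites, R-strain exons carry T
    (the synthetic library couples all three sites; real data need not).
    """
    allele = {"C": "C", "R": "T"}[strain]
    seq = list(TPI_BACKBONE)
    for pos in TPI_EXON_SITE_OFFSETS.values():
        seq[pos] = allele
    start, end = TPI_INTRON_SPAN
    return "".join(seq[:start]) + intron + "".join(seq[end:])


def tpiI4a200_segment_of(label: str) -> str:
    """TpiI4a200 segment (first 60% of the intron) for a library haplotype."""
    return TPI_REFERENCE_SET.sequence_of(label)
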
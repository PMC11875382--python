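"""Host-strain and haplotype typing from COI and Tpi amplicon sequences.

Fall armyworm (*Spodoptera frugiperda*) splits into two morphologically
identical host strains (C-strain / R-strain) distinguishable only by molecular
markers.  Two marker systems are implemented:

* **COIB / CSh** — two polymorphic sites in the 3' half of the mitochondrial
  COI gene (assay names mCOI1164D and mCOI1287R).  The T1164/A1287
  configuration is diagnostic of the R-strain; the four remaining observed
  configurations define the C-strain haplotype classes CSh1-CSh4.
* **Tpi / TpiI4a200** — a C/T polymorphism in the fourth exon of the Z-linked
  Triosephosphate isomerase gene (assay name gTpi183Y) calls the strain, and
  the first ~60% of the downstream intron (TpiI4a200, ~200 bp) serves as a
  high-variation nuclear haplotype marker.

Because Tpi is Z-linked, males carry two copies and direct Sanger sequencing
of heterozygotes yields IUPAC ambiguity codes (or collapses entirely at
indels); such specimens are flagged and excluded from haplotype analysis.

Marker sites are located by unique flanking k-mers rather than absolute
coordinates: the assay numbering is relative to primer positions and no
coordinate system is shipped with the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .iupac import AMBIGUITY_CODES, has_ambiguity, is_dna, revcomp

__all__ = [
    "MarkerError",
    "AmpliconError",
    "SpecimenSequence",
    "MarkerSiteSpec",
    "MarkerConfig",
    "CshCall",
    "TpiCall",
    "TpiSegment",
    "ReferenceHaplotypeSet",
    "HaplotypeTable",
    "extract_amplicon",
    "read_site",
    "classify_coib",
    "classify_tpi_strain",
    "extract_tpiI4a200",
    "flag_heterozygote",
    "enumerate_haplotypes",
    "type_specimens",
    "CSH_ALLELE_MAP",
    "DEFAULT_TPI_STRAIN_MAP",
]


class MarkerError(ValueError):
    """A marker site could not be read from a sequence."""


class AmpliconError(ValueError):
    """In-silico PCR failed: primer not found or ambiguous template."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenSequence:
    """One specimen's amplicon sequence plus collection metadata."""

    specimen_id: str
    gene: str  # "COI" or "Tpi"
    seq: str
    collection_id: str = ""
    year: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.gene not in ("COI", "Tpi"):
            raise ValueError(f"gene must be 'COI' or 'Tpi', got {self.gene!r}")
        if not is_dna(self.seq):
            raise ValueError("seq must be a non-empty IUPAC DNA string")


@dataclass(frozen=True)
class MarkerSiteSpec:
    """A single polymorphic site located by its unique flanking k-mers."""

    gene: str
    site_name: str
    left_flank: str
    right_flank: str
    allowed_alleles: frozenset = frozenset("ACGT")

    def __post_init__(self):
        if len(self.left_flank) < 12 or len(self.right_flank) < 12:
            raise ValueError("flanks must be >= 12 bases")
        if not self.allowed_alleles:
            raise ValueError("allowed_alleles must be non-empty")


@dataclass(frozen=True)
class MarkerConfig:
    """Primer pairs, site definitions and typing options for both assays."""

    coib_fwd: str
    coib_rev: str
    tpi_fwd: str
    tpi_rev: str
    sites: Mapping[str, MarkerSiteSpec]
    exon4_end_flank: str
    exon5_anchor: str
    tpi_strain_map: Mapping[str, str]
    intron_fraction: float = 0.6
    max_mismatch: int = 2


@dataclass(frozen=True)
class CshCall:
    specimen_id: str
    alleles: tuple  # (base at mCOI1164D, base at mCOI1287R)
    label: str  # CSh1..CSh4, R-strain, undetermined


@dataclass(frozen=True)
class TpiCall:
    specimen_id: str
    strain: str  # C, R, undetermined
    intron_segment: str | None
    heterozygous: bool
    haplotype_label: str | None = None

    def __post_init__(self):
        if self.heterozygous and self.haplotype_label is not None:
            raise ValueError("heterozygous specimens cannot carry a haplotype label")


@dataclass(frozen=True)
class TpiSegment:
    """Extracted TpiI4a200 segment plus the full intron length it came from."""

    segment: str
    intron_length: int


@dataclass(frozen=True)
class ReferenceHaplotypeSet:
    """Labelled haplotype sequences with known strain identity."""

    entries: tuple  # of (label, sequence, strain)
    provenance: str = ""

    def __post_init__(self):
        labels = [e[0] for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("reference haplotype labels must be unique")
        for label, seq, strain in self.entries:
            if "-" in seq:
                raise ValueError(f"reference sequence {label} contains gaps")
            if strain not in ("C", "R"):
                raise ValueError(f"strain of {label} must be 'C' or 'R'")

    @property
    def labels(self) -> list:
        return [e[0] for e in self.entries]

    def strain_of(self, label: str) -> str:
        for lab, _, strain in self.entries:
            if lab == label:
                return strain
        raise KeyError(label)

    def sequence_of(self, label: str) -> str:
        for lab, seq, _ in self.entries:
            if lab == label:
                return seq
        raise KeyError(label)

    def subset(self, strain: str) -> "ReferenceHaplotypeSet":
        return ReferenceHaplotypeSet(
            entries=tuple(e for e in self.entries if e[2] == strain),
            provenance=self.provenance,
        )


@dataclass
class HaplotypeTable:
    """Exact-match haplotype grouping: label per specimen plus count table."""

    assignments: dict  # specimen_id -> label
    counts: dict  # label -> count
    sequences: dict  # label -> segment sequence


# ---------------------------------------------------------------------------
# classification maps
# ---------------------------------------------------------------------------

#: CSh class for each (mCOI1164D, mCOI1287R) allele pair.  T1164/A1287 is
#: diagnostic of the R-strain; everything outside the map is "undetermined"
#: (the T/G configuration has never been assigned a class).
CSH_ALLELE_MAP: dict[tuple, str] = {
    ("A", "A"): "CSh1",
    ("A", "G"): "CSh2",
    ("G", "A"): "CSh3",
    ("G", "G"): "CSh4",
    ("T", "A"): "R-strain",
}

#: default strain call for the gTpi183Y exon site
DEFAULT_TPI_STRAIN_MAP: dict[str, str] = {"C": "C", "T": "R"}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _find_primer(seq: str, primer: str, max_mismatch: int) -> tuple | None:
    """Best Hamming-distance hit of *primer* in *seq*.

    Returns (start, mismatches) of the unique best hit (ties by leftmost only
    if strictly better exists; equal best at two places raises).  None if no
    window is within *max_mismatch*.
    """
    k = len(primer)
    best = None  # (mismatches, start)
    tie = False
    for start in range(len(seq) - k + 1):
        mm = sum(1 for a, b in zip(seq[start : start + k], primer) if a != b)
        if mm > max_mismatch:
            continue
        if best is None or mm < best[0]:
            best = (mm, start)
            tie = False
        elif mm == best[0]:
            tie = True
    if best is None:
        return None
    if tie:
        raise AmpliconError(
            f"primer {primer[:8]}... has multiple equal best hits (ambiguous template)"
        )
    return best[1], best[0]


def extract_amplicon(
    seq: str, fwd_primer: str, rev_primer: str, max_mismatch: int = 2
) -> str:
    """In-silico PCR: the subsequence bounded by a primer pair.

    *rev_primer* is given in primer (5'->3') orientation; its reverse
    complement is searched on the given strand.  If the forward primer is not
    found the reverse complement of the template is tried once, mimicking a
    sequence submitted in the opposite orientation.
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be >= 15 bases")
    seq = seq.upper()
    fwd = fwd_primer.upper()
    rev_rc = revcomp(rev_primer)

    fwd_hit = _find_primer(seq, fwd, max_mismatch)
    if fwd_hit is None:
        seq = revcomp(seq)
        fwd_hit = _find_primer(seq, fwd, max_mismatch)
        if fwd_hit is None:
            raise AmpliconError(
                f"forward primer {fwd_primer} not found within "
                f"{max_mismatch} mismatches on either strand"
            )
    rev_hit = _find_primer(seq, rev_rc, max_mismatch)
    if rev_hit is None:
        raise AmpliconError(
            f"reverse primer {rev_primer} not found within {max_mismatch} mismatches"
        )
    start = fwd_hit[0]
    end = rev_hit[0] + len(rev_rc)
    if end <= start:
        raise AmpliconError("reverse primer hit upstream of forward primer")
    return seq[start:end]


def read_site(seq: str, spec: MarkerSiteSpec) -> str:
    """Read the single base bracketed by a site's flanking k-mers.

    Both flanks must occur exactly once and bracket exactly one base.  IUPAC
    ambiguity codes are returned as-is (uppercased) — a 'Y' at gTpi183Y is a
    legitimate heterozygous observation, not an error.
    """
    seq = seq.upper()
    left = spec.left_flank.upper()
    right = spec.right_flank.upper()
    nl = seq.count(left)
    if nl == 0:
        raise MarkerError(f"{spec.site_name}: left flank not found")
    if nl > 1:
        raise MarkerError(f"{spec.site_name}: left flank found {nl} times")
    nr = seq.count(right)
    if nr == 0:
        raise MarkerError(f"{spec.site_name}: right flank not found")
    if nr > 1:
        raise MarkerError(f"{spec.site_name}: right flank found {nr} times")
    left_end = seq.index(left) + len(left)
    right_start = seq.index(right)
    if right_start - left_end != 1:
        raise MarkerError(
            f"{spec.site_name}: flanks bracket {right_start - left_end} bases, expected 1"
        )
    return seq[left_end]


def classify_coib(allele_1164: str, allele_1287: str) -> str:
    """CSh class / strain label for a pair of COIB site alleles.

    Total over IUPAC input: unmapped combinations (including any ambiguity
    code) return "undetermined".
    """
    return CSH_ALLELE_MAP.get((allele_1164.upper(), allele_1287.upper()), "undetermined")


def classify_tpi_strain(
    allele_183: str, strain_map: Mapping[str, str] = DEFAULT_TPI_STRAIN_MAP
) -> str:
    """Host strain from the gTpi183Y exon allele.

    'Y' (C/T ambiguity) is a potential interstrain heterozygote and returns
    "undetermined", as does any allele outside the map.
    """
    base = allele_183.upper()
    if base not in AMBIGUITY_CODES and base not in "ACGT":
        raise ValueError(f"not an IUPAC base: {allele_183!r}")
    return strain_map.get(base, "undetermined")


def extract_tpiI4a200(
    amplicon: str,
    exon4_end_flank: str,
    exon5_anchor: str,
    fraction: float = 0.6,
) -> TpiSegment:
    """Extract the TpiI4a200 segment: the first ~60% of the fourth Tpi intron.

    The intron must start with the canonical GT splice donor immediately after
    the exon-4 end flank and end with the AG acceptor immediately before the
    exon-5 anchor.  Restricting analysis to the 5' 60% of the intron reduces
    the chance that downstream heterozygosity invalidates a read.
    """
    amplicon = amplicon.upper()
    flank = exon4_end_flank.upper()
    anchor = exon5_anchor.upper()
    if amplicon.count(flank) != 1:
        raise MarkerError("exon4 end flank not found exactly once")
    intron_start = amplicon.index(flank) + len(flank)
    if amplicon.count(anchor) != 1:
        raise MarkerError("exon5 anchor not found exactly once")
    intron_end = amplicon.index(anchor)
    if intron_end <= intron_start:
        raise MarkerError("exon5 anchor upstream of intron start")
    intron = amplicon[intron_start:intron_end]
    if not intron.startswith("GT"):
        raise MarkerError("intron does not start with GT splice donor")
    if not intron.endswith("AG"):
        raise MarkerError("intron does not end with AG splice acceptor")
    if len(intron) < 20:
        raise MarkerError(f"intron too short ({len(intron)} < 20 bases)")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    seg_len = int(fraction * len(intron))
    return TpiSegment(segment=intron[:seg_len], intron_length=len(intron))


def flag_heterozygote(segment: str) -> bool:
    """True iff the segment contains at least one IUPAC ambiguity code."""
    if not segment:
        raise ValueError("empty segment")
    return has_ambiguity(segment)


def enumerate_haplotypes(
    segments: Sequence[tuple],
    reference: ReferenceHaplotypeSet | None = None,
) -> HaplotypeTable:
    """Group identical segments into haplotypes and label them.

    Identity is exact string match after uppercasing — segments come from a
    fixed anchored window, so no alignment is needed and length-discordant
    segments are distinct haplotypes by construction.  Segments matching a
    reference entry take its label; the rest get "novel-k" in discovery order.
    """
    if not segments:
        raise ValueError("no segments to enumerate")
    ref_by_seq: dict[str, str] = {}
    if reference is not None:
        for label, seq, _ in reference.entries:
            ref_by_seq[seq.upper()] = label
    assignments: dict[str, str] = {}
    counts: dict[str, int] = {}
    sequences: dict[str, str] = {}
    seen: dict[str, str] = {}
    novel = 0
    for specimen_id, seg in segments:
        key = seg.upper()
        if key in seen:
            label = seen[key]
        elif key in ref_by_seq:
            label = ref_by_seq[key]
            seen[key] = label
        else:
            novel += 1
            label = f"novel-{novel}"
            seen[key] = label
        assignments[specimen_id] = label
        counts[label] = counts.get(label, 0) + 1
        sequences[label] = key
    return HaplotypeTable(assignments=assignments, counts=counts, sequences=sequences)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _call_coi(seq: str, config: MarkerConfig) -> dict:
    a64 = read_site(seq, config.sites["mCOI1164D"])
    a87 = read_site(seq, config.sites["mCOI1287R"])
    label = classify_coib(a64, a87)
    strain = "R" if label == "R-strain" else ("C" if label.startswith("CSh") else "undetermined")
    return {
        "allele_1164": a64,
        "allele_1287": a87,
        "csh_label": label,
        "strain": strain,
    }


def _call_tpi(seq: str, config: MarkerConfig, strict: bool) -> dict:
    out: dict = {}
    for name in ("gTpi165Y", "gTpi168Y", "gTpi183Y"):
        out[f"allele_{name[4:7]}"] = read_site(seq, config.sites[name])
    strain = classify_tpi_strain(out["allele_183"], config.tpi_strain_map)
    if strict:
        calls = [
            classify_tpi_strain(out[f"allele_{n}"], config.tpi_strain_map)
            for n in ("165", "168", "183")
        ]
        concrete = [c for c in calls if c in ("C", "R")]
        # require 2-of-3 concordance with the gTpi183Y call
        if strain in ("C", "R") and sum(c == strain for c in concrete) < 2:
            strain = "undetermined"
    out["strain"] = strain
    return out


def type_specimens(
    specimens: Sequence[SpecimenSequence],
    config: MarkerConfig | None = None,
    tpi_reference: ReferenceHaplotypeSet | None = None,
    strict_tpi: bool = False,
    from_amplicon: bool = True,
) -> pd.DataFrame:
    """Type a batch of specimen sequences; returns one call row per specimen.

    COI rows carry site alleles and the CSh/strain label.  Tpi rows carry the
    exon site alleles, the strain call, the heterozygosity flag, and — for
    non-heterozygous C-strain specimens with a clean intron segment — the
    TpiI4a200 haplotype label (reference label on exact match, else novel-k).

    ``status`` records why a specimen dropped out: "ok", "heterozygous",
    "truncated" (chromatogram collapse at an indel heterozygosity),
    "amplification_failed", or "non_target_strain".
    """
    if config is None:
        from .refseqs import DEFAULT_MARKER_CONFIG

        config = DEFAULT_MARKER_CONFIG
    rows = []
    tpi_segments: list[tuple] = []
    for sp in specimens:
        row = {
            "specimen_id": sp.specimen_id,
            "gene": sp.gene,
            "collection_id": sp.collection_id,
            "year": sp.year,
            "status": "ok",
            "heterozygous": False,
            "tpi_haplotype": None,
        }
        if sp.gene == "COI":
            try:
                seq = (
                    extract_amplicon(sp.seq, config.coib_fwd, config.coib_rev, config.max_mismatch)
                    if from_amplicon
                    else sp.seq
                )
                row.update(_call_coi(seq, config))
            except (AmpliconError, MarkerError) as exc:
                row["status"] = "amplification_failed"
                row["error"] = str(exc)
        else:
            try:
                seq = (
                    extract_amplicon(sp.seq, config.tpi_fwd, config.tpi_rev, config.max_mismatch)
                    if from_amplicon
                    else sp.seq
                )
                row.update(_call_tpi(seq, config, strict_tpi))
            except (AmpliconError, MarkerError) as exc:
                row["status"] = "truncated"
                row["error"] = str(exc)
                rows.append(row)
                continue
            if row["strain"] != "C":
                row["status"] = "non_target_strain"
                rows.append(row)
                continue
            try:
                seg = extract_tpiI4a200(
                    seq, config.exon4_end_flank, config.exon5_anchor, config.intron_fraction
                )
            except MarkerError as exc:
                row["status"] = "truncated"
                row["error"] = str(exc)
                rows.append(row)
                continue
            if flag_heterozygote(seg.segment):
                row["heterozygous"] = True
                row["status"] = "heterozygous"
            else:
                tpi_segments.append((sp.specimen_id, seg.segment))
            row["intron_length"] = seg.intron_length
        rows.append(row)

    df = pd.DataFrame(rows)
    if tpi_segments:
        table = enumerate_haplotypes(tpi_segments, tpi_reference)
        df["tpi_haplotype"] = df["specimen_id"].map(table.assignments).where(
            (df["gene"] == "Tpi") & (df["status"] == "ok"), None
        )
    return df
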
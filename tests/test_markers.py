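"""Marker typing: in-silico PCR, site reading, strain/haplotype classification."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fawkit import refseqs
from fawkit.iupac import IUPAC_SETS, merge_sequences, revcomp
from fawkit.markers import (
    AmpliconError,
    MarkerError,
    classify_coib,
    classify_tpi_strain,
    enumerate_haplotypes,
    extract_amplicon,
    extract_tpiI4a200,
    flag_heterozygote,
    read_site,
    type_specimens,
)

IUPAC = sorted(IUPAC_SETS)


class TestExtractAmplicon:
    def test_exact_amplicon_returned_unchanged(self, marker_config):
        amp = refseqs.coi_amplicon("A", "G")
        assert extract_amplicon(amp, marker_config.coib_fwd, marker_config.coib_rev) == amp

    def test_embedded_amplicon_extracted(self, marker_config):
        amp = refseqs.coi_amplicon("A", "A")
        genomic = "ACGT" * 10 + amp + "TTGCA" * 8
        assert extract_amplicon(genomic, marker_config.coib_fwd, marker_config.coib_rev) == amp

    def test_reverse_complement_template_recovered(self, marker_config):
        amp = refseqs.coi_amplicon("G", "G")
        out = extract_amplicon(revcomp(amp), marker_config.coib_fwd, marker_config.coib_rev)
        assert out == amp

    def test_mutations_beyond_threshold_error(self, marker_config):
        amp = refseqs.coi_amplicon("A", "A")
        # mutate max_mismatch+1 = 3 positions of the forward primer site
        mutated = list(amp)
        for i in (0, 5, 10):
            mutated[i] = "A" if mutated[i] != "A" else "C"
        with pytest.raises(AmpliconError, match="not found"):
            extract_amplicon("".join(mutated), marker_config.coib_fwd,
                             marker_config.coib_rev, max_mismatch=2)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match=">= 15"):
            extract_amplicon("ACGT" * 30, "ACGTACGT", "ACGTACGTACGTACGT")


class TestReadSite:
    def test_reads_embedded_allele(self, marker_config):
        spec = marker_config.sites["mCOI1164D"]
        for base in "ACGT":
            amp = refseqs.coi_amplicon(base, "A")
            assert read_site(amp, spec) == base

    def test_ambiguity_code_returned_as_is(self, marker_config):
        spec = marker_config.sites["gTpi183Y"]
        amp = refseqs.tpi_amplicon(refseqs.CONSENSUS_INTRON, "C")
        pos = refseqs.TPI_EXON_SITE_OFFSETS["gTpi183Y"]
        het = amp[:pos] + "Y" + amp[pos + 1 :]
        assert read_site(het, spec) == "Y"

    def test_missing_flank_errors(self, marker_config):
        spec = marker_config.sites["mCOI1164D"]
        amp = refseqs.coi_amplicon("A", "A")
        broken = amp.replace(spec.left_flank, "")
        with pytest.raises(MarkerError, match="left flank not found"):
            read_site(broken, spec)

    def test_duplicated_flank_errors(self, marker_config):
        spec = marker_config.sites["mCOI1164D"]
        amp = refseqs.coi_amplicon("A", "A") + spec.left_flank
        with pytest.raises(MarkerError, match="found 2 times"):
            read_site(amp, spec)


class TestClassifyCoib:
    @pytest.mark.parametrize(
        "a1164,a1287,expected",
        [
            ("A", "A", "CSh1"),
            ("A", "G", "CSh2"),
            ("G", "A", "CSh3"),
            ("G", "G", "CSh4"),
            ("T", "A", "R-strain"),
            ("T", "G", "undetermined"),
            ("R", "A", "undetermined"),
            ("a", "g", "CSh2"),
        ],
    )
    def test_classification_map(self, a1164, a1287, expected):
        assert classify_coib(a1164, a1287) == expected

    @given(st.sampled_from(IUPAC), st.sampled_from(IUPAC))
    def test_total_over_iupac(self, a, b):
        """Every IUPAC pair gets a label; ambiguity never raises."""
        label = classify_coib(a, b)
        assert label in {"CSh1", "CSh2", "CSh3", "CSh4", "R-strain", "undetermined"}

    def test_exactly_four_cstrain_classes(self):
        labels = [
            classify_coib(a, b) for a, b in itertools.product("AGT", "AG")
        ]
        assert sum(l.startswith("CSh") for l in labels) == 4
        assert labels.count("R-strain") == 1


class TestClassifyTpiStrain:
    def test_default_map(self):
        assert classify_tpi_strain("C") == "C"
        assert classify_tpi_strain("T") == "R"

    def test_heterozygous_site_undetermined(self):
        assert classify_tpi_strain("Y") == "undetermined"

    def test_non_base_rejected(self):
        with pytest.raises(ValueError):
            classify_tpi_strain("X")


class TestExtractTpiSegment:
    def test_sixty_percent_of_335(self, marker_config):
        amp = refseqs.tpi_amplicon(refseqs.CONSENSUS_INTRON, "C")
        seg = extract_tpiI4a200(amp, marker_config.exon4_end_flank,
                                marker_config.exon5_anchor)
        assert seg.intron_length == 335
        assert len(seg.segment) == 201  # floor(0.6 * 335)

    def test_fraction_one_returns_whole_intron(self, marker_config):
        amp = refseqs.tpi_amplicon(refseqs.CONSENSUS_INTRON, "C")
        seg = extract_tpiI4a200(amp, marker_config.exon4_end_flank,
                                marker_config.exon5_anchor, fraction=1.0)
        assert seg.segment == refseqs.CONSENSUS_INTRON

    def test_short_intron_rejected(self, marker_config):
        tiny = "GT" + "ACACAC" + "AG"  # 10 bases
        amp = refseqs.tpi_amplicon(tiny, "C")
        with pytest.raises(MarkerError, match="too short"):
            extract_tpiI4a200(amp, marker_config.exon4_end_flank,
                              marker_config.exon5_anchor)

    def test_truncated_read_errors(self, marker_config):
        amp = refseqs.tpi_amplicon(refseqs.CONSENSUS_INTRON, "C")[:250]
        with pytest.raises(MarkerError):
            extract_tpiI4a200(amp, marker_config.exon4_end_flank,
                              marker_config.exon5_anchor)


class TestFlagHeterozygote:
    @pytest.mark.parametrize(
        "seg,expected",
        [("ACGTACGT", False), ("ACGRACGT", True), ("NNNN", True)],
    )
    def test_flags(self, seg, expected):
        assert flag_heterozygote(seg) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flag_heterozygote("")


class TestEnumerateHaplotypes:
    def test_identical_segments_one_haplotype(self):
        table = enumerate_haplotypes([("s1", "ACGT"), ("s2", "acgt"), ("s3", "ACGT")])
        assert table.counts == {"novel-1": 3}

    def test_single_difference_two_haplotypes(self):
        table = enumerate_haplotypes([("s1", "ACGT"), ("s2", "ACTT")])
        assert len(table.counts) == 2

    def test_reference_label_on_exact_match(self):
        seg = refseqs.tpiI4a200_segment_of("AfrCa2c")
        table = enumerate_haplotypes([("s1", seg)], refseqs.TPI_REFERENCE_SET)
        assert table.assignments["s1"] == "AfrCa2c"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            enumerate_haplotypes([])


class TestPipeline:
    def test_roundtrip_recovers_ground_truth(self, small_population):
        """With zero heterozygosity every typed label equals the simulated truth."""
        spec, specimens = small_population
        calls = type_specimens(specimens, tpi_reference=refseqs.TPI_REFERENCE_SET)
        truth = {s.specimen_id: s.metadata for s in specimens if s.gene == "COI"}
        coi = calls[calls.gene == "COI"].set_index("specimen_id")
        assert (coi.status == "ok").all()
        for sid, md in truth.items():
            assert coi.loc[sid, "csh_label"] == md["true_csh"]
        tpi = calls[calls.gene == "Tpi"].set_index("specimen_id")
        truth_tpi = {s.specimen_id: s.metadata for s in specimens if s.gene == "Tpi"}
        assert (tpi.status == "ok").all()
        for sid, md in truth_tpi.items():
            assert tpi.loc[sid, "tpi_haplotype"] == md["true_tpi_haps"][0]

    def test_amplicon_extraction_invariance(self, small_population):
        """Marker calls agree whether read from raw sequence or extracted amplicon."""
        _, specimens = small_population
        a = type_specimens(specimens, from_amplicon=True)
        b = type_specimens(specimens, from_amplicon=False)
        cols = ["csh_label", "strain", "tpi_haplotype", "heterozygous"]
        assert a[cols].equals(b[cols])

    def test_heterozygotes_flagged_and_excluded(self):
        from fawkit.synthetic import PopulationSpec, gen_population_sequences

        spec = PopulationSpec(
            "Ch16", 60, {"CSh2": 1.0},
            {"AfrCa1c": 0.4, "AfrCa2c": 0.3, "AfrCa2b": 0.3},
            heterozygosity_rate=1.0, seed=3,
        )
        specimens = gen_population_sequences(spec)
        calls = type_specimens(specimens, tpi_reference=refseqs.TPI_REFERENCE_SET)
        tpi = calls[calls.gene == "Tpi"]
        assert set(tpi.status) <= {"heterozygous", "truncated"}
        assert tpi.tpi_haplotype.isna().all()

    def test_interstrain_heterozygote_undetermined(self, marker_config):
        """A C/R Tpi heterozygote shows Y at gTpi183Y and drops out as undetermined."""
        from fawkit.markers import SpecimenSequence

        c_amp = refseqs.tpi_amplicon(refseqs.CONSENSUS_INTRON, "C")
        r_amp = refseqs.tpi_amplicon(
            refseqs.TPI_HAPLOTYPE_LIBRARY.sequence_of("Rs01"), "R"
        )
        merged = merge_sequences(c_amp, r_amp)
        sp = SpecimenSequence("x1", "Tpi", merged, "XX")
        calls = type_specimens([sp])
        assert calls.iloc[0].strain == "undetermined"
        assert calls.iloc[0].status == "non_target_strain"
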
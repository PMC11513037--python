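"""Data model invariants and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgctevo.io import (
    read_segments,
    read_somatic_vcf,
    read_sv_bedpe,
    write_segments,
    write_somatic_vcf,
    write_sv_bedpe,
)
from tgctevo.model import (
    GenomicSegment,
    SomaticVariant,
    SvCall,
    ValidationError,
    compute_loh_fraction,
    compute_ploidy,
    validate_segments,
)


class TestSegmentModel:
    def test_minor_above_major_rejected(self):
        with pytest.raises(ValidationError):
            GenomicSegment("1", 1, 100, major_cn=1, minor_cn=2)

    def test_start_after_end_rejected(self):
        with pytest.raises(ValidationError):
            GenomicSegment("1", 100, 1, 1, 1)

    def test_overlap_detected_with_pair_named(self):
        segs = [
            GenomicSegment("1", 1, 1000, 1, 1),
            GenomicSegment("1", 900, 2000, 2, 1),
        ]
        with pytest.raises(ValidationError, match="900-2000"):
            validate_segments(segs)

    def test_overlap_on_different_chromosomes_allowed(self):
        validate_segments(
            [GenomicSegment("1", 1, 1000, 1, 1), GenomicSegment("2", 1, 1000, 1, 1)]
        )


class TestLohFraction:
    def test_diploid_genome_has_no_loh(self):
        segs = [GenomicSegment("1", 1, 10_000_000, 1, 1)]
        assert compute_loh_fraction(segs) == 0.0

    def test_half_genome_cnloh(self):
        segs = [
            GenomicSegment("1", 1, 10_000_000, 2, 0),
            GenomicSegment("2", 1, 10_000_000, 2, 2),
        ]
        assert compute_loh_fraction(segs) == pytest.approx(0.5)

    def test_sex_chromosomes_excluded_by_default(self):
        segs = [
            GenomicSegment("1", 1, 1_000_000, 1, 1),
            GenomicSegment("X", 1, 50_000_000, 1, 0),
        ]
        assert compute_loh_fraction(segs) == 0.0
        assert compute_loh_fraction(segs, autosomes_only=False) > 0.9

    def test_subclonal_minority_states_excluded(self):
        segs = [
            GenomicSegment("1", 1, 1_000_000, 2, 0, clonal_fraction=0.3),
            GenomicSegment("2", 1, 1_000_000, 1, 1),
        ]
        assert compute_loh_fraction(segs) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        cut=st.integers(min_value=2, max_value=9_999_999),
        minor=st.integers(min_value=0, max_value=2),
    )
    def test_invariant_to_splitting(self, cut, minor):
        """Splitting a segment at any internal breakpoint leaves the
        genome LOH fraction unchanged."""
        whole = [
            GenomicSegment("1", 1, 10_000_000, 2, minor),
            GenomicSegment("2", 1, 10_000_000, 1, 1),
        ]
        split = [
            GenomicSegment("1", 1, cut - 1, 2, minor),
            GenomicSegment("1", cut, 10_000_000, 2, minor),
            GenomicSegment("2", 1, 10_000_000, 1, 1),
        ]
        assert compute_loh_fraction(split) == pytest.approx(
            compute_loh_fraction(whole)
        )


def test_ploidy_is_length_weighted_mean():
    segs = [
        GenomicSegment("1", 1, 30_000_000, 2, 2),  # cn 4
        GenomicSegment("2", 1, 10_000_000, 1, 1),  # cn 2
    ]
    assert compute_ploidy(segs) == pytest.approx((4 * 3 + 2 * 1) / 4, rel=1e-6)


class TestSegmentFile:
    def test_round_trip_identity(self, tmp_path):
        segs = [
            GenomicSegment(str(c), s, s + 999_999, maj, mino, cf)
            for c, s, maj, mino, cf in [
                (1, 1, 2, 1, 1.0), (1, 1_000_001, 2, 2, 1.0), (2, 1, 1, 0, 1.0),
                (3, 5, 2, 0, 0.8), (4, 1, 1, 1, 1.0), (5, 1, 3, 2, 1.0),
                (6, 1, 0, 0, 1.0), (7, 1, 2, 1, 0.5), (8, 1, 1, 1, 1.0),
                (9, 1, 4, 2, 1.0),
            ]
        ]
        path = tmp_path / "segs.tsv"
        write_segments(path, segs, purity=0.75)
        back, pp = read_segments(path)
        assert back == sorted(segs, key=lambda s: (int(s.chrom), s.start))
        assert pp.purity == 0.75

    def test_loh_fraction_recomputed_on_read(self, tmp_path):
        segs = [
            GenomicSegment("1", 1, 1_000_000, 2, 0),
            GenomicSegment("2", 1, 1_000_000, 2, 2),
        ]
        path = tmp_path / "segs.tsv"
        write_segments(path, segs, purity=0.9)
        _, pp = read_segments(path)
        assert pp.loh_fraction == pytest.approx(0.5)

    def test_missing_purity_rejected(self, tmp_path):
        path = tmp_path / "segs.tsv"
        path.write_text("chrom\tstart\tend\tmajor_cn\tminor_cn\tclonal_fraction\n")
        with pytest.raises(ValidationError, match="purity"):
            read_segments(path)


class TestSomaticVcf:
    def test_empty_vcf_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_somatic_vcf(path, [])
        assert read_somatic_vcf(path) == []

    def test_ad_field_mapping(self, tmp_path):
        v = SomaticVariant("1", 12345, "A", "G", 60, 40, 50, 0)
        path = tmp_path / "one.vcf"
        write_somatic_vcf(path, [v])
        (back,) = read_somatic_vcf(path)
        assert back.tumour_ref_depth == 60
        assert back.tumour_alt_depth == 40
        assert back.pos == 12345

    def test_multiallelic_decomposed(self, tmp_path):
        path = tmp_path / "multi.vcf"
        write_somatic_vcf(path, [SomaticVariant("1", 100, "A", "C", 50, 10, 40, 0)])
        # append a second ALT by rewriting the data line
        lines = path.read_text().splitlines()
        lines[-1] = "1\t100\t.\tA\tC,T\t0\t.\t.\tAD\t40,0,0\t50,10,5"
        path.write_text("\n".join(lines) + "\n")
        variants = read_somatic_vcf(path)
        assert [v.alt for v in variants] == ["C", "T"]
        assert [v.tumour_alt_depth for v in variants] == [10, 5]

    def test_round_trip_preserves_records(self, tmp_path):
        variants = [
            SomaticVariant("2", 500 + i, "C", "T", 80 - i, 20 + i, 40, 0,
                           trinucleotide_class="A[C>T]G")
            for i in range(5)
        ]
        path = tmp_path / "rt.vcf"
        write_somatic_vcf(path, variants)
        assert read_somatic_vcf(path) == variants


class TestBedpe:
    def test_zero_based_conversion(self, tmp_path):
        calls = [SvCall("1", 100, "1", 5100, "DEL", "delly", 10, 100, 0)]
        path = tmp_path / "sv.bedpe"
        write_sv_bedpe(path, calls)
        text = path.read_text().split("\t")
        assert text[1] == "99"  # bedpe start = pos - 1
        (back,) = read_sv_bedpe(path)
        assert back.pos1 == 100

    def test_round_trip_five_calls(self, tmp_path):
        calls = [
            SvCall("1", 1000, "1", 9000, "DEL", "delly", 10, 100, 0, "a"),
            SvCall("2", 500, "2", 700_000, "TD", "lumpy", 5, 90, 0, "b"),
            SvCall("3", 100, "5", 200, "TRANS", "manta", 8, 80, 0, "c"),
            SvCall("4", 10, "4", 99_999, "H2HINV", "delly", 7, 70, 0, "d"),
            SvCall("5", 42, "5", 4242, "T2TINV", "manta", 6, 60, 0, "e"),
        ]
        path = tmp_path / "five.bedpe"
        write_sv_bedpe(path, calls)
        back = read_sv_bedpe(path)
        assert back == calls

    def test_interchromosomal_trans_accepted(self):
        call = SvCall("1", 500, "7", 100, "TRANS", "delly")
        assert call.is_interchromosomal
        assert call.size is None

    def test_unknown_sv_type_rejected(self):
        with pytest.raises(ValidationError, match="DEL, TD"):
            SvCall("1", 1, "1", 2, "INS", "delly")
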
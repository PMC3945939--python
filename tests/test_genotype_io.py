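"""Readers (VCF, HapMap, simple), the binary cache, and reader equivalence."""

import numpy as np
import pytest

import snp2tree as st
from snp2tree.errors import CacheError, EmptyInputError, FormatError
from snp2tree.io import CACHE_MAGIC, HAPMAP_COLUMNS

M = st.MISSING

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1
chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.
chr1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t1|1\t0|0
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVcf:
    def test_hand_parsed_dosages(self, tmp_path):
        gm, report = st.read_vcf(_write(tmp_path, "a.vcf", VCF_FIXTURE))
        assert gm.samples == ["sampleA", "sampleB"]
        assert np.array_equal(gm.calls, [[0, 1, 2], [2, M, 0]])
        assert report.records_in == report.records_retained == 3
        assert [s.site_id for s in gm.sites] == ["rs1", "rs2", "rs3"]

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        text = VCF_FIXTURE + "chr1\t400\trs4\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\n"
        gm, report = st.read_vcf(_write(tmp_path, "b.vcf", text))
        assert gm.n_sites == 3
        assert report.multiallelic == 1
        assert report.conserved()

    def test_indel_skipped(self, tmp_path):
        text = VCF_FIXTURE + "chr1\t400\trs4\tAT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        _, report = st.read_vcf(_write(tmp_path, "c.vcf", text))
        assert report.not_snp == 1 and report.conserved()

    def test_half_call_is_missing(self, tmp_path):
        text = VCF_FIXTURE.replace("0/1\t./.", "./1\t0/0")
        gm, _ = st.read_vcf(_write(tmp_path, "d.vcf", text))
        assert gm.calls[0, 1] == M

    def test_zero_records_is_empty_input_error(self, tmp_path):
        header = "\n".join(VCF_FIXTURE.splitlines()[:3]) + "\n"
        with pytest.raises(EmptyInputError):
            st.read_vcf(_write(tmp_path, "e.vcf", header))

    def test_headerless_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            st.read_vcf(_write(tmp_path, "f.vcf", "chr1\t100\trs1\tA\tG\n"))


def hapmap_text(rows, samples=("s1", "s2", "s3")):
    head = "\t".join(HAPMAP_COLUMNS + list(samples))
    return head + "\n" + "\n".join("\t".join(r) for r in rows) + "\n"


def hm_row(rsid, alleles, chrom, pos, cells):
    return [rsid, alleles, chrom, pos, "+", "NA", "NA", "NA", "NA", "NA", "NA"] + cells


class TestReadHapmap:
    def test_hand_parsed_dosages(self, tmp_path):
        text = hapmap_text([
            hm_row("rs1", "A/G", "1", "100", ["AA", "AG", "GG"]),
            hm_row("rs2", "C/T", "1", "200", ["CC", "NN", "TT"]),
        ])
        gm, report = st.read_hapmap(_write(tmp_path, "a.hmp.txt", text))
        assert np.array_equal(gm.calls, [[0, 0], [1, M], [2, 2]])
        assert report.records_retained == 2

    def test_single_letter_is_homozygous(self, tmp_path):
        text = hapmap_text([hm_row("rs1", "A/G", "1", "100", ["A", "G", "AG"])])
        gm, _ = st.read_hapmap(_write(tmp_path, "b.hmp.txt", text))
        assert list(gm.calls[:, 0]) == [0, 2, 1]

    def test_three_allele_row_skipped(self, tmp_path):
        text = hapmap_text([
            hm_row("rs1", "A/G", "1", "100", ["AA", "GG", "TT"]),
            hm_row("rs2", "A/G", "1", "200", ["AA", "AG", "GG"]),
        ])
        gm, report = st.read_hapmap(_write(tmp_path, "c.hmp.txt", text))
        assert gm.n_sites == 1 and report.multiallelic == 1 and report.conserved()

    def test_letter_outside_pair_becomes_missing_with_warning(self, tmp_path):
        # observed alleles stay <= 2 but a cell contradicts the declared pair
        text = hapmap_text([hm_row("rs1", "A/G", "1", "100", ["AA", "TT", "AA"])])
        with pytest.warns(UserWarning, match="not in alleles"):
            gm, _ = st.read_hapmap(_write(tmp_path, "d.hmp.txt", text))
        assert gm.calls[1, 0] == M

    def test_too_few_columns_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            st.read_hapmap(_write(tmp_path, "e.hmp.txt", "rs#\talleles\tchrom\npos\n"))


class TestReadSimple:
    def test_hand_parsed(self, tmp_path):
        gm, _ = st.read_simple(_write(tmp_path, "a.txt", "chr1\t100\t0\t1\t2\n"))
        assert gm.n_sites == 1
        assert list(gm.calls[:, 0]) == [0, 1, 2]
        assert (gm.sites[0].ref, gm.sites[0].alt) == ("A", "G")  # placeholders

    def test_missing_codes(self, tmp_path):
        gm, _ = st.read_simple(_write(tmp_path, "b.txt", "chr1\t100\t.\tNA\t2\n"))
        assert list(gm.calls[:, 0]) == [M, M, 2]

    def test_header_with_sample_names(self, tmp_path):
        gm, _ = st.read_simple(
            _write(tmp_path, "c.txt", "chrom\tpos\talpha\tbeta\nchr1\t100\t0\t2\n"))
        assert gm.samples == ["alpha", "beta"]

    def test_out_of_domain_dosage_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="line"):
            st.read_simple(_write(tmp_path, "d.txt", "chr1\t100\t0\t3\t2\n"))


class TestCache:
    def test_round_trip_small(self, small_gm, tmp_path):
        p = tmp_path / "gm.cache"
        st.write_cache(small_gm, p)
        assert st.read_cache(p).equals(small_gm)

    def test_round_trip_large_synthetic(self, tmp_path):
        tree = st.simulate_tree(20, 1)
        gm, _ = st.simulate_genotypes(
            tree, st.SimConfig(n_taxa=20, n_sites=10_000, missing_rate=0.03, seed=1))
        p = tmp_path / "big.cache"
        st.write_cache(gm, p)
        assert st.read_cache(p).equals(gm)

    def test_version_mismatch(self, small_gm, tmp_path):
        p = tmp_path / "gm.cache"
        st.write_cache(small_gm, p)
        blob = bytearray(p.read_bytes())
        blob[8:10] = (99).to_bytes(2, "little")
        p.write_bytes(bytes(blob))
        with pytest.raises(CacheError, match="version"):
            st.read_cache(p)

    def test_truncation_detected(self, small_gm, tmp_path):
        p = tmp_path / "gm.cache"
        st.write_cache(small_gm, p)
        p.write_bytes(p.read_bytes()[:-2])
        with pytest.raises(CacheError, match="truncated"):
            st.read_cache(p)

    def test_bad_magic(self, tmp_path):
        p = tmp_path / "junk.cache"
        p.write_bytes(b"NOTACACHE" + b"\0" * 20)
        with pytest.raises(CacheError, match="magic"):
            st.read_cache(p)


class TestReaderEquivalence:
    def test_same_genotypes_parse_identically_from_all_formats(self, synthetic_gm, tmp_path):
        gm = synthetic_gm
        parsed = {}
        for fmt, reader in [("vcf", st.read_vcf), ("hapmap", st.read_hapmap),
                            ("simple", st.read_simple)]:
            p = tmp_path / f"x.{fmt}"
            st.write_fixture(gm, fmt, p)
            parsed[fmt], report = reader(p)
            assert report.conserved()
        assert parsed["vcf"].equals(gm)
        assert parsed["hapmap"].equals(gm)
        # simple carries dosages only; alleles are placeholders
        assert np.array_equal(parsed["simple"].calls, gm.calls)
        assert parsed["simple"].samples == gm.samples

    def test_sites_sorted_by_chrom_pos(self, tmp_path):
        text = VCF_FIXTURE + "chr0\t150\trs9\tA\tC\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        gm, _ = st.read_vcf(_write(tmp_path, "g.vcf", text))
        keys = [(s.chrom, s.pos) for s in gm.sites]
        assert keys == sorted(keys)
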
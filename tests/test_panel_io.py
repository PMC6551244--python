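import numpy as np
import pytest

from mpbwt import (
    AlphabetViolationError,
    HaplotypePanel,
    PanelFormatError,
    panel_from_matrix,
    read_matrix,
    read_vcf,
    write_matches,
    write_matrix,
)
from mpbwt.matching import MatchRecord

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(tmp_path, body, samples):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    path = tmp_path / "panel.vcf"
    path.write_text(VCF_HEADER + cols + "\t" + "\t".join(samples) + "\n" + body)
    return path


class TestReadMatrix:
    def test_observed_alphabet_is_column_max_plus_one(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 1 2\n1 1 0\n0 1 0\n2 0 1\n")
        panel = read_matrix(p)
        assert (panel.M, panel.N) == (4, 3)
        assert panel.site_alphabet_sizes.tolist() == [3, 2, 3]

    def test_fixed_alphabet_applies_everywhere(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 0\n0 0\n")
        panel = read_matrix(p, alphabet_size=3)
        assert panel.site_alphabet_sizes.tolist() == [3, 3]

    def test_fixed_alphabet_rejects_large_codes(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 3\n0 0\n")
        with pytest.raises(AlphabetViolationError):
            read_matrix(p, alphabet_size=3)

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("", "empty"),
            ("0 1\n0\n", "ragged"),
            ("0 x\n", "non-integer"),
            ("0 -1\n", "negative"),
        ],
    )
    def test_malformed_input_is_named(self, tmp_path, text, fragment):
        p = tmp_path / "bad.txt"
        p.write_text(text)
        with pytest.raises(PanelFormatError, match=fragment):
            read_matrix(p)

    def test_roundtrip_fixed_alphabet(self, tmp_path):
        rng = np.random.default_rng(0)
        panel = panel_from_matrix(rng.integers(0, 4, size=(6, 9)), alphabet_size=4)
        p = tmp_path / "rt.txt"
        write_matrix(panel, p)
        back = read_matrix(p, alphabet_size=4)
        assert np.array_equal(back.alleles, panel.alleles)
        assert np.array_equal(back.site_alphabet_sizes, panel.site_alphabet_sizes)


class TestPanelInvariants:
    def test_alphabet_must_cover_observed_codes(self):
        with pytest.raises(AlphabetViolationError):
            HaplotypePanel(
                alleles=np.array([[0, 2]]),
                site_alphabet_sizes=np.array([1, 2]),
            )

    def test_alphabet_may_exceed_observed_codes(self):
        panel = HaplotypePanel(
            alleles=np.array([[0, 0]]),
            site_alphabet_sizes=np.array([5, 5]),
        )
        assert panel.max_alphabet_size == 5

    def test_at_least_one_haplotype(self):
        with pytest.raises(PanelFormatError):
            HaplotypePanel(
                alleles=np.zeros((0, 3), dtype=int),
                site_alphabet_sizes=np.array([1, 1, 1]),
            )


class TestReadVCF:
    def test_multiallelic_phased_decoding(self, tmp_path):
        body = "1\t100\t.\tA\tC,G\t.\tPASS\t.\tGT\t1|2\n"
        panel = read_vcf(write_vcf(tmp_path, body, ["S1"]))
        assert panel.alleles.tolist() == [[1], [2]]
        assert panel.site_alphabet_sizes.tolist() == [3]
        assert panel.site_ids == ["1:100"]

    def test_biallelic_all_ref(self, tmp_path):
        body = (
            "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|0\t0|0\n"
            "1\t200\t.\tT\tG\t.\tPASS\t.\tGT\t0|0\t0|0\n"
        )
        panel = read_vcf(write_vcf(tmp_path, body, ["S1", "S2"]))
        assert panel.alleles.shape == (4, 2)
        assert not panel.alleles.any()
        assert panel.site_alphabet_sizes.tolist() == [2, 2]

    def test_missing_rejected_by_default_naming_site(self, tmp_path):
        body = "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t.|.\n"
        with pytest.raises(PanelFormatError, match="1:100"):
            read_vcf(write_vcf(tmp_path, body, ["S1"]))

    def test_missing_as_extra_allele_grows_alphabet(self, tmp_path):
        body = "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t.|.\t0|1\n"
        panel = read_vcf(
            write_vcf(tmp_path, body, ["S1", "S2"]), missing_policy="extra_allele"
        )
        assert panel.alleles[:, 0].tolist() == [2, 2, 0, 1]
        assert panel.site_alphabet_sizes.tolist() == [3]

    def test_unphased_het_rejected(self, tmp_path):
        body = "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
        with pytest.raises(PanelFormatError, match="unphased"):
            read_vcf(write_vcf(tmp_path, body, ["S1"]))

    def test_half_call_rejected(self, tmp_path):
        body = "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t.|1\n"
        with pytest.raises(PanelFormatError, match="half-call"):
            read_vcf(write_vcf(tmp_path, body, ["S1"]))

    def test_region_filter(self, tmp_path):
        body = (
            "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\n"
            "1\t200\t.\tT\tG\t.\tPASS\t.\tGT\t1|1\n"
            "2\t150\t.\tT\tG\t.\tPASS\t.\tGT\t1|0\n"
        )
        panel = read_vcf(write_vcf(tmp_path, body, ["S1"]), region="1:150-250")
        assert panel.site_ids == ["1:200"]


class TestWriteMatches:
    def test_line_format_and_length(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_matches([MatchRecord(0, 2, 0, 2)], p)
        header, line = p.read_text().splitlines()
        assert header.startswith("#hap_i")
        assert line == "0\t2\t0\t2\t2"

    def test_empty_report(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_matches([], p)
        assert p.read_text().splitlines()[1:] == []

    def test_sorted_by_end_start_then_pair(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_matches(
            [
                MatchRecord(0, 3, 1, 4),
                MatchRecord(0, 2, 1, 4),
                MatchRecord(1, 2, 0, 4),
                MatchRecord(0, 1, 0, 2),
            ],
            p,
        )
        rows = [tuple(map(int, l.split()[:4])) for l in p.read_text().splitlines()[1:]]
        assert rows == [(0, 1, 0, 2), (1, 2, 0, 4), (0, 2, 1, 4), (0, 3, 1, 4)]
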
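"""Reading ANNOVAR tables / annotated VCFs and writing reports."""

import pandas as pd
import pytest

from exotier.annotation_io import (
    decode_predictor_call,
    read_annotated_vcf,
    read_annovar_table,
    sort_report,
    write_report,
)
from exotier.exceptions import FormatError, InputError
from exotier.models import Genotype


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestAnnovarTable:
    def test_sentinels_map_to_absent(self, tmp_path):
        path = write_lines(
            tmp_path / "t.tsv",
            [
                "Chr\tStart\tRef\tAlt\tExonicFunc.refGene\tExAC_ALL\tgnomAD_exome_ALL",
                "1\t100\tA\tT\tstopgain\t.\tNA",
            ],
        )
        cohort = read_annovar_table(path)
        v = cohort.variants[0]
        assert v.exonic_func == "stopgain"
        assert v.pop_freqs == {}

    def test_fixture_round_trip(self, fixture_result):
        cohort = read_annovar_table(fixture_result.paths["annovar_tsv"])
        truth = fixture_result.cohort
        assert cohort.samples == truth.samples
        assert len(cohort.variants) == len(truth.variants)
        by_key = {v.key: v for v in cohort.variants}
        for tv in truth.variants:
            v = by_key[tv.key]
            assert v.genotypes == tv.genotypes
            assert v.gene == tv.gene
            assert v.exonic_func == tv.exonic_func
            assert v.func_region == tv.func_region
            assert v.pop_freqs == tv.pop_freqs
            assert v.predictor_calls == tv.predictor_calls
            assert v.clinvar_sig == tv.clinvar_sig
            assert v.clinvar_status == tv.clinvar_status
            assert v.domain_annotation == tv.domain_annotation
            assert v.hom_count == tv.hom_count
            assert bool(v.repeat_region) == bool(tv.repeat_region)

    def test_missing_coordinate_columns_is_format_error(self, tmp_path):
        path = write_lines(
            tmp_path / "t.tsv", ["Chr\tStart\tGene.refGene", "1\t100\tBRCA2"]
        )
        with pytest.raises(FormatError, match="ref.*alt|alt.*ref"):
            read_annovar_table(path)

    def test_unreadable_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_annovar_table(tmp_path / "absent.tsv")

    def test_csv_dialect(self, tmp_path):
        path = write_lines(
            tmp_path / "t.csv",
            ["Chr,Start,Ref,Alt,Gene.refGene,S1,S2", "2,500,G,C,TP53,0/1,0/0"],
        )
        cohort = read_annovar_table(path)
        assert cohort.samples == ["S1", "S2"]
        assert cohort.variants[0].genotypes["S1"] is Genotype.HET

    def test_unrecognized_columns_passthrough(self, tmp_path):
        path = write_lines(
            tmp_path / "t.tsv",
            ["Chr\tStart\tRef\tAlt\tMyCustomScore", "1\t100\tA\tT\t0.7"],
        )
        v = read_annovar_table(path).variants[0]
        assert v.passthrough == {"MyCustomScore": "0.7"}


VCF_HEADER = [
    "##fileformat=VCFv4.2",
    "##contig=<ID=1>",
    '##INFO=<ID=Gene.refGene,Number=.,Type=String,Description="x">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


class TestVcfReading:
    def test_genotype_decoding(self, tmp_path):
        path = write_lines(
            tmp_path / "t.vcf",
            VCF_HEADER
            + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
               "1\t100\t.\tA\tT\t.\tPASS\tGene.refGene=BRCA2\tGT\t0/1\t0/0\t1/1"],
        )
        cohort = read_annotated_vcf(path, dialect="annovar")
        v = cohort.variants[0]
        assert v.carriers() == ["s1", "s3"]
        assert v.gene == "BRCA2"

    def test_multiallelic_decomposition_conserves_carriers(self, tmp_path):
        path = write_lines(
            tmp_path / "t.vcf",
            VCF_HEADER
            + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4",
               "1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2\t./1"],
        )
        cohort = read_annotated_vcf(path, dialect="annovar")
        assert len(cohort.variants) == 2
        first, second = cohort.variants
        assert (first.alt, second.alt) == ("T", "G")
        # ./1 decodes missing, so s4 is not a carrier of either allele
        assert set(first.carriers()) == {"s1", "s2"}
        assert set(second.carriers()) == {"s2", "s3"}
        original_carriers = {"s1", "s2", "s3"}
        assert set(first.carriers()) | set(second.carriers()) == original_carriers

    def test_vep_dialect_requires_csq_header(self, tmp_path):
        path = write_lines(
            tmp_path / "t.vcf",
            VCF_HEADER
            + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
               "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1"],
        )
        with pytest.raises(FormatError, match="CSQ"):
            read_annotated_vcf(path, dialect="vep")

    def test_haploid_genotype_warns_and_is_missing(self, tmp_path):
        path = write_lines(
            tmp_path / "t.vcf",
            VCF_HEADER
            + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
               "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1\t0/1"],
        )
        with pytest.warns(UserWarning, match="non-diploid"):
            cohort = read_annotated_vcf(path, dialect="annovar")
        assert cohort.variants[0].genotypes["s1"] is Genotype.MISSING
        assert cohort.variants[0].genotypes["s2"] is Genotype.HET

    def test_vep_fixture_round_trip(self, fixture_result):
        cohort = read_annotated_vcf(fixture_result.paths["vep_vcf"], dialect="vep")
        truth = {v.key: v for v in fixture_result.cohort.variants}
        assert len(cohort.variants) == len(truth)
        for v in cohort.variants:
            tv = truth[v.key]
            assert v.genotypes == tv.genotypes
            assert v.gene == tv.gene
            assert v.exonic_func == tv.exonic_func
            assert v.pop_freqs == tv.pop_freqs
            assert v.clinvar_sig == tv.clinvar_sig
            assert v.clinvar_status == tv.clinvar_status


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("D", "deleterious"), ("T", "tolerated"), ("P", "deleterious"),
        ("N", "tolerated"), ("A", "deleterious"), (".", "unknown"),
        ("deleterious(0.01)", "deleterious"), ("tolerated(0.62)", "tolerated"),
        ("probably_damaging(0.96)", "deleterious"), ("benign(0.05)", "tolerated"),
        ("U", "unknown"),
    ],
)
def test_predictor_call_decoding(raw, expected):
    assert decode_predictor_call(raw) == expected


class TestReportWriting:
    def report(self):
        return pd.DataFrame(
            {
                "Chr": ["2", "1", "1"],
                "Pos": [50, 200, 100],
                "Ref": ["A", "C", "G"],
                "Alt": ["T", "G", "A"],
                "Gene": ["B", "A", "C"],
                "Extra": ["x", "y", "z"],
            }
        )

    def test_rows_sorted_by_coordinates(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report(self.report(), path)
        back = pd.read_csv(path, sep="\t")
        assert list(back["Pos"]) == [100, 200, 50]
        assert list(back["Chr"].astype(str)) == ["1", "1", "2"]

    def test_round_trip_identical(self, tmp_path):
        path = tmp_path / "r.tsv"
        df = sort_report(self.report())
        write_report(df, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(df.columns)
        assert back["Extra"].tolist() == df["Extra"].tolist()

    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report(self.report().iloc[0:0], path)
        assert path.read_text().strip() == "Chr\tPos\tRef\tAlt\tGene\tExtra"

    def test_unwritable_path_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            write_report(self.report(), tmp_path / "no_such_dir" / "r.tsv")

    def test_workbook_output(self, tmp_path):
        from exotier.annotation_io import write_workbook

        path = tmp_path / "r.xlsx"
        write_workbook({"main": self.report(), "by_gene": pd.DataFrame({"Gene": ["A"]})}, path)
        sheets = pd.read_excel(path, sheet_name=None)
        assert set(sheets) == {"main", "by_gene"}
        assert len(sheets["main"]) == 3
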
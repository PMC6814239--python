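"""Gene burden, by-sample ranking, filters and the EnrichR interface."""

import json

import pandas as pd
import pytest

from exotier.enrichr import DEFAULT_LIBRARY, EnrichrClient
from exotier.exceptions import EnrichrUnavailable, InputError
from exotier.reporting import (
    by_sample_report,
    filter_by_disease_term,
    filter_by_genes,
    filter_by_pathway,
    gene_burden,
    load_gene_descriptions,
    load_pathways,
)


def burden_frame(rows):
    return pd.DataFrame(
        rows, columns=["Gene", "Posterior_probability", "Cohort_carriers",
                       "Cohort_noncarriers"]
    )


class TestGeneBurden:
    def test_formula(self):
        df = burden_frame([("G1", 0.9, 3, 7), ("G1", 0.85, 2, 8), ("G2", 0.95, 1, 9)])
        out = gene_burden(df, flags_list=frozenset(), gene_lengths={})
        assert dict(zip(out.Gene, out.Burden)) == pytest.approx(
            {"G1": 0.9 * 3 + 0.85 * 2, "G2": 0.95}
        )
        assert out.Gene.tolist() == ["G1", "G2"]  # descending burden

    def test_variant_at_floor_excluded(self):
        df = burden_frame([("G1", 0.80, 5, 5), ("G2", 0.8000001, 5, 5)])
        out = gene_burden(df, flags_list=frozenset(), gene_lengths={})
        assert out.Gene.tolist() == ["G2"]

    def test_gene_without_counted_variants_absent(self):
        df = burden_frame([("G1", 0.5, 5, 5)])
        assert gene_burden(df, flags_list=frozenset(), gene_lengths={}).empty

    def test_order_invariance(self):
        rows = [("G1", 0.9, 3, 7), ("G2", 0.95, 1, 9), ("G1", 0.85, 2, 8)]
        a = gene_burden(burden_frame(rows), flags_list=frozenset(), gene_lengths={})
        b = gene_burden(burden_frame(rows[::-1]), flags_list=frozenset(), gene_lengths={})
        pd.testing.assert_frame_equal(a, b)

    def test_flags_warning(self):
        df = burden_frame([("TTN", 0.9, 2, 8)])
        out = gene_burden(df, flags_list=frozenset({"TTN"}), gene_lengths={})
        assert "flags_gene" in out.Warnings[0]

    def test_excess_carrier_warning(self):
        df = burden_frame([("G1", 0.9, 10, 0)])
        out = gene_burden(df, flags_list=frozenset(), gene_lengths={})
        assert "excess_carriers" in out.Warnings[0]

    def test_long_gene_warning_is_advisory(self):
        df = burden_frame([("TTN", 0.9, 2, 8), ("TP53", 0.9, 2, 8)])
        lengths = {"TTN": 100_000, "TP53": 1_200, "ACTB": 1_100, "KRAS": 600}
        out = gene_burden(df, flags_list=frozenset(), gene_lengths=lengths)
        warn = dict(zip(out.Gene, out.Warnings))
        assert "long_gene" in warn["TTN"] and "long_gene" not in warn["TP53"]
        # the warning never changes the score
        assert dict(zip(out.Gene, out.Burden))["TTN"] == pytest.approx(1.8)


class TestBySample:
    def result(self, fixture_result):
        from exotier.annotation_io import read_annovar_table
        from exotier.pipeline import classify_cohort
        from exotier.trio import Pedigree

        cohort = read_annovar_table(fixture_result.paths["annovar_tsv"])
        ped = Pedigree.from_tsv(fixture_result.paths["pedigree"])
        return classify_cohort(cohort, pedigree=ped)

    def test_rows_only_for_carriers_and_ranked(self, fixture_result):
        result = self.result(fixture_result)
        table = by_sample_report(result, top_k=5)
        for sample, group in table[table.Rank != ""].groupby("Sample"):
            posteriors = group.sort_values("Rank")["Posterior_probability"].tolist()
            assert posteriors == sorted(posteriors, reverse=True)
            for _, row in group.iterrows():
                rec = next(
                    r for r in result.records
                    if r.variant.key == (str(row.Chr), int(row.Pos), row.Ref, row.Alt)
                )
                assert rec.variant.genotypes[sample].is_carrier

    def test_default_keeps_only_pathogenic_threshold(self, fixture_result):
        result = self.result(fixture_result)
        table = by_sample_report(result)
        filled = table[table.Rank != ""]
        assert (filled.Posterior_probability >= result.thresholds.pathogenic_cut).all()

    def test_empty_samples_still_listed(self, fixture_result):
        result = self.result(fixture_result)
        table = by_sample_report(result)
        assert set(table.Sample) == set(result.cohort.samples)

    def test_tie_break_by_coordinates(self, fixture_result):
        result = self.result(fixture_result)
        table = by_sample_report(result, top_k=10)
        s4 = table[(table.Sample == "S04") & (table.Rank != "")]
        # equal posteriors (PS1+PP3+PP5 vs PS4+PM2) break by chromosome order
        equal = s4[s4.Posterior_probability.astype(float).round(9)
                   == round(0.8999100280514164, 9)]
        if len(equal) == 2:
            assert equal.sort_values("Rank").Chr.astype(str).tolist() == ["3", "17"]


MAIN = pd.DataFrame(
    {
        "Gene": ["BRCA2", "TP53", "MLH1", "ACTB"],
        "Chr": ["13", "17", "3", "7"],
        "Pos": [1, 2, 3, 4],
    }
)


class TestFilters:
    def test_gene_filter_case_insensitive(self):
        assert filter_by_genes(MAIN, {"BRCA2"}).Gene.tolist() == ["BRCA2"]
        assert filter_by_genes(MAIN, "brca2").Gene.tolist() == ["BRCA2"]

    def test_gene_filter_keeps_columns(self):
        out = filter_by_genes(MAIN, {"TP53"})
        assert list(out.columns) == list(MAIN.columns)

    def test_gene_filter_from_file(self, tmp_path):
        f = tmp_path / "genes.txt"
        f.write_text("tp53\nmlh1\n")
        assert filter_by_genes(MAIN, str(f)).Gene.tolist() == ["TP53", "MLH1"]

    def test_empty_gene_list_is_an_error(self):
        with pytest.raises(InputError, match="empty"):
            filter_by_genes(MAIN, set())

    def test_no_match_yields_header_only(self):
        out = filter_by_genes(MAIN, {"NOSUCHGENE"})
        assert out.empty and list(out.columns) == list(MAIN.columns)

    def test_pathway_filter(self):
        out = filter_by_pathway(MAIN, "Mismatch repair")
        assert out.Gene.tolist() == ["MLH1"]

    def test_unknown_pathway_suggests_near_matches(self):
        with pytest.raises(InputError, match="[Mm]ismatch"):
            filter_by_pathway(MAIN, "Mismach repair")

    def test_disease_term_filter(self):
        out = filter_by_disease_term(MAIN, "autosomal dominant")
        assert "ACTB" not in out.Gene.tolist()
        assert {"BRCA2", "TP53", "MLH1"} <= set(out.Gene)

    def test_disease_term_no_match(self):
        assert filter_by_disease_term(MAIN, "zebrafish fin regeneration").empty

    def test_empty_term_is_an_error(self):
        with pytest.raises(InputError):
            filter_by_disease_term(MAIN, "  ")

    def test_bundled_snapshots_load(self):
        pathways = load_pathways()
        assert "Pathways in cancer" in pathways
        descriptions = load_gene_descriptions()
        assert "autosomal dominant" in descriptions["TP53"].lower()


class TestEnrichrClient:
    def mock_transport(self, calls):
        def transport(url, data=None):
            calls.append((url, data))
            if url.endswith("/addList"):
                return json.dumps({"userListId": 42, "shortId": "x"}).encode()
            return json.dumps(
                {DEFAULT_LIBRARY: [[1, "DNA repair", 1e-6, 2.0, 30.0,
                                    ["BRCA2", "MLH1"], 1e-5, 0, 0]]}
            ).encode()

        return transport

    def test_mocked_round_trip_and_default_library(self):
        calls = []
        client = EnrichrClient(transport=self.mock_transport(calls))
        table = client.enrich(["BRCA2", "MLH1"])
        assert table.Term.tolist() == ["DNA repair"]
        assert DEFAULT_LIBRARY in calls[1][0]  # default library used

    def test_empty_gene_list_raises(self):
        client = EnrichrClient(transport=self.mock_transport([]))
        with pytest.raises(EnrichrUnavailable, match="empty"):
            client.enrich([])

    def test_network_failure_degrades(self):
        def broken(url, data=None):
            raise OSError("no route to host")

        with pytest.raises(EnrichrUnavailable, match="failed"):
            EnrichrClient(transport=broken).enrich(["BRCA2"])
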
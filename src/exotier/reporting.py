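"""Filtered, by-sample and by-gene reports over a classified cohort.

All filters return row-subsets of the main report with identical columns, so
filtered reports can feed any tool that consumes the main report.  The
by-gene report ranks genes by the burden score

    burden(gene) = sum over the gene's variants with P_i > 0.80 of P_i * N_i

where P_i is the posterior probability of pathogenicity and N_i the number of
cohort samples carrying the variant; variants with P_i <= 0.80 are excluded.
The score is a sum of probabilities, not a statistic with a null model, so
advisory warnings mark entries likely to be inflated: FLAGS genes, very long
genes, and variants carried by almost the whole cohort (poorly mapped or
pseudo-autosomal artifacts).
"""

from __future__ import annotations

import csv
import difflib
from importlib import resources
from pathlib import Path

import pandas as pd

from .acmg import load_flags_genes
from .exceptions import InputError
from .models import chrom_sort_key
from .pipeline import CohortResult

WARN_FLAGS = "flags_gene"
WARN_LONG = "long_gene"
WARN_EXCESS = "excess_carriers"


def _data_path(name: str):
    return resources.files("exotier").joinpath("data", name)


def _read_two_column_tsv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    for row in rows[1:]:  # first row is the header
        out[row[0].strip()] = row[1].strip()
    return out


def load_pathways(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Bundled pathway -> gene-set snapshot (or a user table in the same layout)."""
    raw = _read_two_column_tsv(path or _data_path("pathways.synthetic.tsv"))
    return {
        name: frozenset(g.strip().upper() for g in genes.split(",") if g.strip())
        for name, genes in raw.items()
    }


def load_gene_descriptions(path: str | Path | None = None) -> dict[str, str]:
    """Bundled gene -> description snapshot used by the disease-term filter."""
    return {
        gene.upper(): desc
        for gene, desc in _read_two_column_tsv(
            path or _data_path("gene_descriptions.synthetic.tsv")
        ).items()
    }


def load_gene_lengths(path: str | Path | None = None) -> dict[str, int]:
    """Bundled gene -> approximate coding length (bp) for the long-gene warning."""
    return {
        gene.upper(): int(length)
        for gene, length in _read_two_column_tsv(
            path or _data_path("gene_coding_lengths.synthetic.tsv")
        ).items()
    }


# --- by-gene burden -----------------------------------------------------------------


def gene_burden(
    report: pd.DataFrame,
    flags_list: frozenset[str] | None = None,
    carrier_warn_fraction: float = 0.9,
    posterior_floor: float = 0.80,
    gene_lengths: dict[str, int] | None = None,
    long_gene_quantile: float = 0.99,
) -> pd.DataFrame:
    """Per-gene probability-weighted carrier burden, sorted descending.

    Only variants with posterior strictly above ``posterior_floor`` count
    (a variant at exactly 0.80 is excluded); genes with no counted variant
    are absent.  Warnings are advisory text and never alter the score.
    """
    flags_list = flags_list if flags_list is not None else load_flags_genes()
    gene_lengths = gene_lengths if gene_lengths is not None else load_gene_lengths()
    long_cut = None
    if gene_lengths:
        lengths = sorted(gene_lengths.values())
        long_cut = lengths[min(len(lengths) - 1, int(long_gene_quantile * len(lengths)))]

    counted = report[report["Posterior_probability"] > posterior_floor]
    entries = []
    for gene, group in counted.groupby("Gene", sort=False):
        if not gene:
            continue
        burden = float((group["Posterior_probability"] * group["Cohort_carriers"]).sum())
        warnings_set = []
        if gene.upper() in flags_list:
            warnings_set.append(WARN_FLAGS)
        if long_cut is not None and gene_lengths.get(gene.upper(), 0) >= long_cut:
            warnings_set.append(WARN_LONG)
        genotyped = group["Cohort_carriers"] + group["Cohort_noncarriers"]
        fractions = group["Cohort_carriers"] / genotyped.where(genotyped > 0, other=1)
        if (fractions > carrier_warn_fraction).any():
            warnings_set.append(WARN_EXCESS)
        entries.append(
            {
                "Gene": gene,
                "Burden": burden,
                "N_variants_counted": int(len(group)),
                "Warnings": ", ".join(warnings_set),
            }
        )
    out = pd.DataFrame(entries, columns=["Gene", "Burden", "N_variants_counted", "Warnings"])
    return out.sort_values(
        ["Burden", "Gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# --- by-sample report ---------------------------------------------------------------


def by_sample_report(result: CohortResult, top_k: int | None = None) -> pd.DataFrame:
    """Per-sample ranking of carried variants by descending posterior.

    With ``top_k=None`` each sample's section keeps every carried variant at
    or above the pathogenic threshold; otherwise the top ``top_k`` carried
    variants regardless of posterior.  Ties break by (chrom, pos).  Samples
    carrying nothing reportable are still listed (one empty row).
    """
    columns = ["Sample", "Rank"] + [c for c in result.report.columns]
    rows = []
    for sample in result.cohort.samples:
        carried = [
            rec for rec in result.records if rec.variant.genotypes[sample].is_carrier
        ]
        carried.sort(
            key=lambda r: (
                -r.classification.posterior,
                chrom_sort_key(r.variant.chrom),
                r.variant.pos,
            )
        )
        if top_k is None:
            carried = [
                r for r in carried
                if r.classification.posterior >= result.thresholds.pathogenic_cut
            ]
        else:
            carried = carried[:top_k]
        if not carried:
            rows.append({"Sample": sample, "Rank": ""})
            continue
        key_of = {rec.variant.key: i for i, rec in enumerate(result.records)}
        for rank, rec in enumerate(carried, start=1):
            row = result.report.iloc[key_of[rec.variant.key]].to_dict()
            row.update({"Sample": sample, "Rank": rank})
            rows.append(row)
    # object dtype keeps integer coordinates intact next to empty rows
    table = pd.DataFrame(rows, columns=columns, dtype=object)
    return table.where(pd.notna(table), "")


# --- filtered reports ---------------------------------------------------------------


def _as_gene_set(genes) -> frozenset[str]:
    if isinstance(genes, (str, Path)) and Path(str(genes)).is_file():
        text = Path(genes).read_text().replace(",", "\n")
        genes = [g.strip() for g in text.splitlines()]
    elif isinstance(genes, str):
        genes = [g.strip() for g in genes.split(",")]
    return frozenset(g.upper() for g in genes if g)


def filter_by_genes(report: pd.DataFrame, genes) -> pd.DataFrame:
    """Rows whose gene is in the given set (case-insensitive); ``genes`` may
    be a set, a comma-separated string or a path to a one-gene-per-line file.
    An empty gene list is an error (distinct from no matches, which yields a
    header-only report)."""
    gene_set = _as_gene_set(genes)
    if not gene_set:
        raise InputError("the gene list is empty")
    mask = report["Gene"].astype(str).str.upper().isin(gene_set)
    return report[mask].reset_index(drop=True)


def filter_by_pathway(
    report: pd.DataFrame,
    pathway_name: str,
    pathway_table: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Rows whose gene belongs to the named pathway (offline snapshot)."""
    table = pathway_table if pathway_table is not None else load_pathways()
    if pathway_name not in table:
        near = difflib.get_close_matches(pathway_name, list(table), n=3, cutoff=0.4)
        hint = f"; close matches: {', '.join(near)}" if near else ""
        raise InputError(f"unknown pathway {pathway_name!r}{hint}")
    genes = table[pathway_name]
    mask = report["Gene"].astype(str).str.upper().isin(genes)
    return report[mask].reset_index(drop=True)


def filter_by_disease_term(
    report: pd.DataFrame,
    term: str,
    gene_descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rows whose gene description contains the term (case-insensitive
    substring), e.g. 'autosomal dominant' or 'colorectal cancer'."""
    if not term or not term.strip():
        raise InputError("the disease search term is empty")
    descriptions = (
        gene_descriptions if gene_descriptions is not None else load_gene_descriptions()
    )
    needle = term.strip().lower()
    matching = frozenset(g for g, d in descriptions.items() if needle in d.lower())
    mask = report["Gene"].astype(str).str.upper().isin(matching)
    return report[mask].reset_index(drop=True)
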
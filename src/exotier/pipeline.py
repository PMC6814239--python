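"""End-to-end cohort classification: criteria, trio, enrichment, posterior.

``classify_cohort`` runs the full assessment on one cohort:

1. with a pedigree, de-novo detection runs on the complete cohort (parental
   genotypes are needed), then unaffected parents are removed from all
   downstream analysis;
2. the annotation-derived criteria are assigned per variant, PS2 is added for
   de-novo variants and PS4 from the control-free enrichment test (skipped
   for BA1 variants — stand-alone benign and case enrichment are mutually
   exclusive — and for single-sample cohorts);
3. the combined criteria yield the categorical ACMG class and the posterior
   probability of pathogenicity;
4. everything is assembled into the main report table with deterministic row
   and column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .acmg import EngineConfig, ReferenceTables, assign_criteria
from .annotation_io import FREQ_ALIASES, order_columns
from .bayes import ClassificationResult, ModelParams, Thresholds, classify
from .enrichment import EnrichmentResult, EnrichmentThresholds, assign_ps4
from .models import AnnotatedVariant, Cohort, CriteriaSet, variant_sort_key
from .trio import Pedigree, detect_de_novo, strip_healthy_parents


@dataclass
class VariantRecord:
    """One classified variant, aligned with one row of the main report."""

    variant: AnnotatedVariant
    criteria: CriteriaSet
    classification: ClassificationResult
    enrichment: EnrichmentResult | None
    de_novo_trios: tuple[str, ...]


@dataclass
class CohortResult:
    """Output of :func:`classify_cohort`: the report plus aligned records."""

    cohort: Cohort  # after healthy-parent removal
    records: list[VariantRecord]
    report: pd.DataFrame
    thresholds: Thresholds
    params: ModelParams

    @property
    def pathogenic_genes(self) -> list[str]:
        """Genes with at least one variant above the pathogenic threshold."""
        mask = self.report["Posterior_probability"] >= self.thresholds.pathogenic_cut
        genes = self.report.loc[mask, "Gene"].dropna()
        return sorted({g for g in genes if g})


def _report_row(rec: VariantRecord) -> dict:
    v = rec.variant
    e = rec.enrichment
    row = {
        "Chr": v.chrom,
        "Pos": v.pos,
        "Ref": v.ref,
        "Alt": v.alt,
        "Gene": v.gene or "",
        "ACMG_criteria": ", ".join(rec.criteria.sorted()),
        "ACMG_class": rec.classification.category,
        "Posterior_probability": rec.classification.posterior,
        "Probability_verdict": rec.classification.verdict,
        "De_novo_trios": ";".join(rec.de_novo_trios),
        "Cohort_carriers": e.cohort_carriers if e else sum(
            1 for g in v.genotypes.values() if g.is_carrier
        ),
        "Cohort_noncarriers": e.cohort_noncarriers if e else sum(
            1 for g in v.genotypes.values() if g.name == "HOM_REF"
        ),
        "Control_carriers": e.control.n_c if e else None,
        "Control_noncarriers": e.control.N_c if e else None,
        "Odds_ratio": e.odds_ratio if e else None,
        "P_value": e.p_value if e else None,
        "PS4": bool(e.ps4) if e else False,
        "Func_region": v.func_region or "",
        "Exonic_func": v.exonic_func or "",
        "AA_change": v.aa_change or "",
        "ClinVar_sig": v.clinvar_sig or "",
        "ClinVar_status": v.clinvar_status or "",
        "Domain": v.domain_annotation or "",
        "Evidence_notes": "; ".join(
            f"{label}: {note}" for label, note in sorted(rec.criteria.evidence_notes.items())
        ),
    }
    for label in FREQ_ALIASES:
        if label in v.pop_freqs:
            row[label] = v.pop_freqs[label]
    for name, value in v.passthrough.items():
        row.setdefault(name, value)
    return row


def classify_cohort(
    cohort: Cohort,
    tables: ReferenceTables | None = None,
    config: EngineConfig | None = None,
    params: ModelParams | None = None,
    thresholds: Thresholds | None = None,
    enrichment_thresholds: EnrichmentThresholds | None = None,
    pedigree: Pedigree | None = None,
    control_db: str | None = None,
) -> CohortResult:
    """Run the full assessment and build the main report."""
    tables = tables if tables is not None else ReferenceTables.load_default()
    config = config if config is not None else EngineConfig()
    params = params if params is not None else ModelParams()
    thresholds = thresholds if thresholds is not None else Thresholds()

    de_novo: dict[int, tuple[str, ...]] = {}
    if pedigree is not None:
        pedigree.validate(cohort.samples)
        for i, v in enumerate(cohort.variants):
            hit, trios = detect_de_novo(v, pedigree)
            if hit:
                de_novo[i] = tuple(trios)
        cohort = strip_healthy_parents(cohort, pedigree)

    records = []
    for i, v in enumerate(cohort.variants):
        criteria = assign_criteria(v, tables, config)
        if i in de_novo:
            criteria.add("PS2", f"de novo in trio(s) {', '.join(de_novo[i])}")
        enrichment = None
        if "BA1" not in criteria and cohort.n_samples >= 2:
            enrichment = assign_ps4(v, control_db, enrichment_thresholds)
            if enrichment is not None and enrichment.ps4:
                criteria.add(
                    "PS4",
                    f"cohort enrichment OR={enrichment.odds_ratio:.3g}, "
                    f"p={enrichment.p_value:.3g}",
                )
        classification = classify(criteria, params, thresholds)
        records.append(
            VariantRecord(
                variant=v,
                criteria=criteria,
                classification=classification,
                enrichment=enrichment,
                de_novo_trios=de_novo.get(i, ()),
            )
        )

    records.sort(key=lambda r: variant_sort_key(r.variant))
    report = pd.DataFrame([_report_row(r) for r in records])
    if not report.empty:
        report = order_columns(report)
    return CohortResult(
        cohort=cohort, records=records, report=report,
        thresholds=thresholds, params=params,
    )
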
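"""Synthetic annotated cohorts with known ground truth.

Every blueprint names the ACMG criteria a variant is meant to trigger; the
generator constructs annotations that realize exactly that pattern, assigns
deterministic genotypes (no sampling noise, so truth is exact), and emits the
same cohort in three layouts — ANNOVAR-style TSV, ANNOVAR-annotated VCF and
VEP-annotated VCF — plus a pedigree table and a truth object enumerating the
expected criteria, classification, PS4 flags, de-novo calls and gene burdens.
A separate randomized mode supplies unstructured variants for property tests.

Blueprints demanding contradictory evidence (for example BA1 together with
PM2) are rejected up front.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .acmg import EngineConfig, ReferenceTables, assign_criteria
from .bayes import ModelParams, Thresholds, classify
from .enrichment import EnrichmentThresholds
from .exceptions import FixtureSpecError
from .models import (
    AnnotatedVariant,
    Cohort,
    CriteriaSet,
    Genotype,
    parse_protein_change,
    variant_sort_key,
)
from .trio import Pedigree, PedigreeEntry

# pairs of criteria no single variant can carry at once
_CONFLICTS = (
    frozenset({"BA1", "PM2"}),
    frozenset({"BA1", "PS4"}),
    frozenset({"BA1", "BS1"}),
    frozenset({"PS1", "PM5"}),
    frozenset({"PM4", "BP3"}),
    frozenset({"PP3", "BP4"}),
    frozenset({"PS3", "PP5"}),
    frozenset({"BS3", "BP6"}),
    frozenset({"PS3", "BS3"}),
    frozenset({"PP5", "BP6"}),
)

_ASSERTED_STATUS = "criteria provided, multiple submitters, no conflicts"
_NO_ASSERTION_STATUS = "no assertion criteria provided"
_EXPERT_STATUS = "reviewed by expert panel"


@dataclass(frozen=True)
class VariantBlueprint:
    """One intended variant: the criteria it must trigger plus its carriers."""

    name: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    criteria: frozenset[str]
    het_carriers: tuple[str, ...] = ()
    hom_carriers: tuple[str, ...] = ()
    control_maf: float | None = None
    de_novo_trio: str | None = None
    aa_change: tuple[int, str, str] | None = None  # (residue, ref AA, alt AA)
    cdna: str | None = None


@dataclass(frozen=True)
class FixtureSpec:
    n_samples: int = 10
    blueprints: tuple[VariantBlueprint, ...] = ()
    seed: int = 0

    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class VariantTruth:
    key: tuple[str, int, str, str]
    criteria: frozenset[str]
    category: str
    posterior: float
    verdict: str
    ps4: bool
    de_novo_trios: tuple[str, ...]
    downstream_carriers: int


@dataclass
class CohortTruth:
    samples_downstream: list[str]
    variants: dict[tuple[str, int, str, str], VariantTruth]
    gene_burden: dict[str, float]
    n_report_rows: int


@dataclass
class FixtureResult:
    cohort: Cohort
    pedigree: Pedigree | None
    truth: CohortTruth
    paths: dict[str, Path] = field(default_factory=dict)


def default_blueprints() -> tuple[VariantBlueprint, ...]:
    """Twelve variants jointly covering all 21 assignable criteria."""
    bp = VariantBlueprint
    return (
        # rare pathogenic variants are singletons: a second carrier in a
        # cohort this small is already genuine enrichment and earns PS4
        bp("lof_stopgain", "BRCA2", "13", 32338000, "C", "T",
           frozenset({"PVS1", "PM2"}), het_carriers=("S04",)),
        bp("known_missense", "TP53", "17", 7675088, "G", "A",
           frozenset({"PS1", "PP3", "PP5"}), het_carriers=("S04",),
           aa_change=(175, "R", "H"), cdna="c.524G>A"),
        bp("novel_at_hotspot", "TP53", "17", 7675100, "G", "T",
           frozenset({"PM5", "PM2"}), het_carriers=("S06",),
           aa_change=(175, "R", "L"), cdna="c.524G>T"),
        bp("reviewed_pathogenic", "SCN1A", "2", 166245425, "C", "T",
           frozenset({"PS3", "PM1", "PP2"}), het_carriers=("S04",)),
        bp("cohort_enriched", "MLH1", "3", 37047000, "A", "G",
           frozenset({"PS4", "PM2"}),
           het_carriers=("S04", "S05", "S06", "S07", "S08"), control_maf=3.23e-5),
        bp("de_novo_lof", "PTEN", "10", 87933000, "G", "T",
           frozenset({"PVS1", "PS2", "PM2"}), de_novo_trio="trio1"),
        bp("common_benign", "ALDH2", "12", 111803000, "G", "A",
           frozenset({"BA1"}),
           het_carriers=("S04", "S05", "S06", "S07", "S08", "S09")),
        bp("frequent_with_homs", "CFTR", "7", 117559500, "T", "C",
           frozenset({"BS1", "BS2", "BS3"}), het_carriers=("S05", "S06", "S07")),
        bp("tolerated_missense", "TTN", "2", 178528000, "C", "G",
           frozenset({"BP1", "BP4"}), het_carriers=("S09",)),
        bp("silent_benign", "ACTB", "7", 5530600, "A", "G",
           frozenset({"BP7", "BP6"}), het_carriers=("S10",)),
        bp("inframe_del", "MYH7", "14", 23424000, "TCTG", "T",
           frozenset({"PM4", "PM2"}), het_carriers=("S07",)),
        bp("repeat_ins", "MUC16", "19", 8950000, "A", "ACAG",
           frozenset({"BP3"}), het_carriers=("S08",)),
    )


def default_pedigree() -> Pedigree:
    return Pedigree(
        [
            PedigreeEntry("S01", "trio1", "father", False),
            PedigreeEntry("S02", "trio1", "mother", False),
            PedigreeEntry("S03", "trio1", "child", True),
        ]
    )


def default_spec(seed: int = 0) -> FixtureSpec:
    return FixtureSpec(n_samples=10, blueprints=default_blueprints(), seed=seed)


# --- blueprint realization ----------------------------------------------------------


def _set(fields: dict, key: str, value, blueprint_name: str) -> None:
    if key in fields and fields[key] != value:
        raise FixtureSpecError(
            f"blueprint {blueprint_name!r}: criteria demand contradictory "
            f"{key} ({fields[key]!r} vs {value!r})"
        )
    fields[key] = value


def _check_conflicts(blueprint: VariantBlueprint) -> None:
    for pair in _CONFLICTS:
        if pair <= blueprint.criteria:
            raise FixtureSpecError(
                f"blueprint {blueprint.name!r} demands contradictory evidence: "
                f"{sorted(pair)}"
            )
    unknown = blueprint.criteria - {
        "PVS1", "PS1", "PS2", "PS3", "PS4", "PM1", "PM2", "PM4", "PM5",
        "PP2", "PP3", "PP5", "BA1", "BS1", "BS2", "BS3", "BP1", "BP3",
        "BP4", "BP6", "BP7",
    }
    if unknown:
        raise FixtureSpecError(
            f"blueprint {blueprint.name!r} names unassignable criteria: {sorted(unknown)}"
        )


def _realize(
    blueprint: VariantBlueprint,
    samples: list[str],
    pedigree: Pedigree | None,
    tables: ReferenceTables,
    config: EngineConfig,
) -> AnnotatedVariant:
    _check_conflicts(blueprint)
    b = blueprint
    fields: dict = {}
    crit = b.criteria

    if "PVS1" in crit:
        if b.gene.upper() not in tables.lof_intolerant_genes:
            raise FixtureSpecError(f"{b.name}: PVS1 needs a LOF-intolerant gene, not {b.gene}")
        _set(fields, "exonic_func", "stopgain", b.name)
    if "PP2" in crit and b.gene.upper() not in tables.missense_constrained_genes:
        raise FixtureSpecError(f"{b.name}: PP2 needs a missense-constrained gene, not {b.gene}")
    if "BP1" in crit and b.gene.upper() not in tables.truncating_mechanism_genes:
        raise FixtureSpecError(f"{b.name}: BP1 needs a truncating-mechanism gene, not {b.gene}")
    if ("PS1" in crit or "PM5" in crit) and b.aa_change is None:
        raise FixtureSpecError(f"{b.name}: PS1/PM5 need an aa_change")
    if "PS3" in crit:
        _set(fields, "clinvar_sig", "Pathogenic", b.name)
        _set(fields, "clinvar_status", _ASSERTED_STATUS, b.name)
    if "PP5" in crit:
        _set(fields, "clinvar_sig", "Pathogenic", b.name)
        _set(fields, "clinvar_status", _NO_ASSERTION_STATUS, b.name)
    if "BS3" in crit:
        _set(fields, "clinvar_sig", "Benign", b.name)
        _set(fields, "clinvar_status", _EXPERT_STATUS, b.name)
    if "BP6" in crit:
        _set(fields, "clinvar_sig", "Benign", b.name)
        _set(fields, "clinvar_status", _NO_ASSERTION_STATUS, b.name)
    if "PM1" in crit:
        _set(fields, "domain_annotation", "Ion transport domain", b.name)
    if "PM4" in crit:
        _set(fields, "exonic_func", "nonframeshift deletion", b.name)
    if "BP3" in crit:
        _set(fields, "exonic_func", "nonframeshift insertion", b.name)
        _set(fields, "repeat_region", True, b.name)
    if "BP7" in crit:
        _set(fields, "exonic_func", "synonymous SNV", b.name)
    if "PP3" in crit:
        _set(fields, "predictor_calls",
             {"sift": "deleterious", "polyphen2_hdiv": "deleterious",
              "mutationtaster": "deleterious", "lrt": "tolerated"}, b.name)
    if "BP4" in crit:
        _set(fields, "predictor_calls",
             {"sift": "tolerated", "polyphen2_hdiv": "tolerated",
              "mutationtaster": "tolerated", "lrt": "deleterious"}, b.name)
    if "BS2" in crit:
        _set(fields, "hom_count", 3, b.name)
    if "BA1" in crit:
        fields.setdefault("pop_freqs", {})["gnomad_exome_all"] = 0.12
    if "BS1" in crit:
        fields.setdefault("pop_freqs", {})["gnomad_exome_all"] = 0.02
    if "PS2" in crit and b.de_novo_trio is None:
        raise FixtureSpecError(f"{b.name}: PS2 needs a de_novo_trio")
    if "PS4" in crit:
        if b.control_maf is None:
            raise FixtureSpecError(f"{b.name}: PS4 needs a control_maf")
        if len(b.het_carriers) + len(b.hom_carriers) + (b.de_novo_trio is not None) < 2:
            raise FixtureSpecError(f"{b.name}: PS4 needs at least 2 carriers")

    if b.control_maf is not None:
        fields.setdefault("pop_freqs", {})["gnomad_exome_all"] = b.control_maf
    if "PM2" in crit:
        bad = {k: f for k, f in fields.get("pop_freqs", {}).items()
               if f >= config.rare_threshold}
        if bad:
            raise FixtureSpecError(f"{b.name}: PM2 conflicts with frequencies {bad}")
    elif not fields.get("pop_freqs"):
        # a baseline frequency keeps PM2 from firing unintentionally
        fields["pop_freqs"] = {"exac_all": 5e-4}

    fields.setdefault("exonic_func", "nonsynonymous SNV")
    fields.setdefault("func_region", "exonic")
    if b.aa_change is not None:
        residue, ref_aa, alt_aa = b.aa_change
        cdna = b.cdna or "c.0A>A"
        fields["aa_change"] = (
            f"{b.gene}:NM_000000:exon1:{cdna}:p.{ref_aa}{residue}{alt_aa}"
        )
        fields["cdna_change"] = cdna

    genotypes = {s: Genotype.HOM_REF for s in samples}
    for s in b.het_carriers:
        if s not in genotypes:
            raise FixtureSpecError(f"{b.name}: carrier {s} not in the sample list")
        genotypes[s] = Genotype.HET
    for s in b.hom_carriers:
        if s not in genotypes:
            raise FixtureSpecError(f"{b.name}: carrier {s} not in the sample list")
        genotypes[s] = Genotype.HOM_ALT
    if b.de_novo_trio is not None:
        if pedigree is None:
            raise FixtureSpecError(f"{b.name}: de_novo_trio set but no pedigree")
        roles = pedigree.trios()[b.de_novo_trio]
        genotypes[roles["child"].sample] = Genotype.HET
        genotypes[roles["father"].sample] = Genotype.HOM_REF
        genotypes[roles["mother"].sample] = Genotype.HOM_REF

    return AnnotatedVariant(
        chrom=b.chrom, pos=b.pos, ref=b.ref, alt=b.alt, gene=b.gene,
        genotypes=genotypes, **fields,
    )


def build_cohort(
    spec: FixtureSpec,
    tables: ReferenceTables | None = None,
    config: EngineConfig | None = None,
) -> tuple[Cohort, Pedigree | None, CohortTruth]:
    """Realize a spec in memory and derive its truth object."""
    tables = tables if tables is not None else ReferenceTables.load_default()
    config = config if config is not None else EngineConfig()
    blueprints = spec.blueprints or default_blueprints()
    samples = spec.sample_names()
    pedigree = default_pedigree() if any(b.de_novo_trio for b in blueprints) else None
    if pedigree is not None:
        missing = {e.sample for e in pedigree.entries} - set(samples)
        if missing:
            raise FixtureSpecError(f"pedigree samples {sorted(missing)} exceed n_samples")

    variants = [_realize(b, samples, pedigree, tables, config) for b in blueprints]
    cohort = Cohort(samples=samples, variants=variants)

    healthy = pedigree.healthy_parents() if pedigree is not None else set()
    downstream = [s for s in samples if s not in healthy]

    params, thresholds = ModelParams(), Thresholds()
    truth_variants: dict[tuple[str, int, str, str], VariantTruth] = {}
    burden: dict[str, float] = {}
    for b, v in zip(blueprints, variants):
        criteria = CriteriaSet(set(b.criteria))
        result = classify(criteria, params, thresholds)
        carriers = sum(1 for s in downstream if v.genotypes[s].is_carrier)
        de_novo = (b.de_novo_trio,) if b.de_novo_trio else ()
        truth_variants[v.key] = VariantTruth(
            key=v.key,
            criteria=b.criteria,
            category=result.category,
            posterior=result.posterior,
            verdict=result.verdict,
            ps4="PS4" in b.criteria,
            de_novo_trios=de_novo,
            downstream_carriers=carriers,
        )
        if result.posterior > 0.80 and carriers > 0:
            burden[b.gene] = burden.get(b.gene, 0.0) + result.posterior * carriers

    truth = CohortTruth(
        samples_downstream=downstream,
        variants=truth_variants,
        gene_burden=burden,
        n_report_rows=len(variants),
    )
    return cohort, pedigree, truth


# --- serialization ------------------------------------------------------------------

_FREQ_COLUMNS = [
    ("exac_all", "ExAC_ALL"),
    ("gnomad_exome_all", "gnomAD_exome_ALL"),
    ("gnomad_genome_all", "gnomAD_genome_ALL"),
    ("thousand_genomes", "1000g2015aug_all"),
    ("esp6500", "esp6500siv2_all"),
]
_PRED_COLUMNS = [
    ("sift", "SIFT_pred"),
    ("polyphen2_hdiv", "Polyphen2_HDIV_pred"),
    ("mutationtaster", "MutationTaster_pred"),
    ("lrt", "LRT_pred"),
]

_PRED_LETTER = {"deleterious": {"lrt": "D"}, "tolerated": {"lrt": "N"}}


def _pred_letter(label: str, call: str) -> str:
    special = _PRED_LETTER.get(call, {})
    if label in special:
        return special[label]
    return "D" if call == "deleterious" else "T"


_GT_TEXT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _fmt(value) -> str:
    return "." if value is None else repr(value) if isinstance(value, float) else str(value)


def write_annovar_tsv(cohort: Cohort, path: str | Path) -> None:
    """ANNOVAR multianno-style TSV with per-sample genotype columns."""
    anno_cols = (
        ["Chr", "Start", "End", "Ref", "Alt", "Func.refGene", "Gene.refGene",
         "ExonicFunc.refGene", "AAChange.refGene"]
        + [c for _, c in _FREQ_COLUMNS]
        + [c for _, c in _PRED_COLUMNS]
        + ["CLNSIG", "CLNREVSTAT", "Interpro_domain", "genomicSuperDups",
           "dbscSNV_ADA_SCORE", "gnomAD_exome_nhomalt"]
    )
    lines = ["\t".join(anno_cols + cohort.samples)]
    for v in cohort.variants:
        row = [
            v.chrom, str(v.pos), str(v.pos + len(v.ref) - 1), v.ref, v.alt,
            _fmt(v.func_region), _fmt(v.gene), _fmt(v.exonic_func), _fmt(v.aa_change),
        ]
        row += [_fmt(v.pop_freqs.get(k)) for k, _ in _FREQ_COLUMNS]
        row += [
            _pred_letter(k, v.predictor_calls[k]) if k in v.predictor_calls else "."
            for k, _ in _PRED_COLUMNS
        ]
        row += [
            _fmt(v.clinvar_sig), _fmt(v.clinvar_status), _fmt(v.domain_annotation),
            "Score=0.95;Name=segdup" if v.repeat_region else ".",
            _fmt(v.splice_pred), _fmt(v.hom_count),
        ]
        row += [_GT_TEXT[v.genotypes[s]] for s in cohort.samples]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _vcf_escape(value: str) -> str:
    return (
        value.replace(";", "\\x3b").replace("=", "\\x3d")
        .replace(",", "\\x2c").replace(" ", "_")
    )


def _vcf_header(cohort: Cohort, info_lines: list[str]) -> list[str]:
    contigs = sorted({v.chrom for v in cohort.variants})
    return (
        ["##fileformat=VCFv4.2"]
        + [f"##contig=<ID={c}>" for c in contigs]
        + info_lines
        + ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
        + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
           + "\t".join(cohort.samples)]
    )


def write_annovar_vcf(cohort: Cohort, path: str | Path) -> None:
    """VCF with ANNOVAR-style key=value INFO annotations."""
    body: list[tuple[AnnotatedVariant, list[tuple[str, object]]]] = []
    used_keys: list[str] = []
    for v in sorted(cohort.variants, key=variant_sort_key):
        pairs = [
            ("Func.refGene", v.func_region), ("Gene.refGene", v.gene),
            ("ExonicFunc.refGene", v.exonic_func), ("AAChange.refGene", v.aa_change),
        ]
        pairs += [(col, v.pop_freqs.get(k)) for k, col in _FREQ_COLUMNS]
        pairs += [
            (col, _pred_letter(k, v.predictor_calls[k]) if k in v.predictor_calls else None)
            for k, col in _PRED_COLUMNS
        ]
        pairs += [
            ("CLNSIG", v.clinvar_sig), ("CLNREVSTAT", v.clinvar_status),
            ("Interpro_domain", v.domain_annotation),
            ("genomicSuperDups", "Score=0.95;Name=segdup" if v.repeat_region else None),
            ("dbscSNV_ADA_SCORE", v.splice_pred), ("gnomAD_exome_nhomalt", v.hom_count),
        ]
        pairs = [(k, val) for k, val in pairs if val is not None]
        body.append((v, pairs))
        for k, _ in pairs:
            if k not in used_keys:
                used_keys.append(k)
    info_lines = [
        f'##INFO=<ID={k},Number=.,Type=String,Description="ANNOVAR annotation">'
        for k in used_keys
    ]
    lines = _vcf_header(cohort, info_lines)
    for v, pairs in body:
        info = ";".join(f"{k}={_vcf_escape(_fmt(val))}" for k, val in pairs)
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", info or ".", "GT"]
        row += [_GT_TEXT[v.genotypes[s]] for s in cohort.samples]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


_EXONIC_TO_VEP = {
    "stopgain": "stop_gained",
    "frameshift insertion": "frameshift_variant",
    "frameshift deletion": "frameshift_variant",
    "nonsynonymous SNV": "missense_variant",
    "synonymous SNV": "synonymous_variant",
    "nonframeshift insertion": "inframe_insertion",
    "nonframeshift deletion": "inframe_deletion",
    "stoploss": "stop_lost",
    "startloss": "start_lost",
}

_CSQ_FIELDS = [
    "Allele", "Consequence", "IMPACT", "SYMBOL", "Protein_position", "Amino_acids",
    "HGVSc", "gnomADe_AF", "gnomADg_AF", "ExAC_AF", "AF", "ESP_AF",
    "SIFT", "PolyPhen", "MutationTaster_pred", "LRT_pred",
    "ClinVar_CLNSIG", "ClinVar_CLNREVSTAT", "DOMAINS", "RepeatRegion",
    "ada_score", "gnomAD_nhomalt",
]

_CSQ_FREQ = {
    "gnomADe_AF": "gnomad_exome_all",
    "gnomADg_AF": "gnomad_genome_all",
    "ExAC_AF": "exac_all",
    "AF": "thousand_genomes",
    "ESP_AF": "esp6500",
}


def _csq_escape(value: str) -> str:
    return value.replace(", ", "&").replace(",", "&").replace(" ", "_")


def _vep_consequence(v: AnnotatedVariant) -> str:
    if v.func_region == "splicing":
        return "splice_donor_variant"
    if v.exonic_func in _EXONIC_TO_VEP:
        return _EXONIC_TO_VEP[v.exonic_func]
    return {"intronic": "intron_variant", "UTR3": "3_prime_UTR_variant",
            "UTR5": "5_prime_UTR_variant", "intergenic": "intergenic_variant"}.get(
        v.func_region or "", "intergenic_variant")


def _vep_pred(v: AnnotatedVariant, label: str, vep_style: str) -> str:
    call = v.predictor_calls.get(label)
    if call is None:
        return ""
    if vep_style == "sift":
        return "deleterious(0.01)" if call == "deleterious" else "tolerated(0.62)"
    if vep_style == "polyphen":
        return "probably_damaging(0.96)" if call == "deleterious" else "benign(0.05)"
    return _pred_letter(label, call)


def write_vep_vcf(cohort: Cohort, path: str | Path) -> None:
    """VCF carrying the cohort's annotations in a VEP CSQ INFO field."""
    from .annotation_io import vep_allele  # local import avoids a cycle

    info_lines = [
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
        'from Ensembl VEP. Format: ' + "|".join(_CSQ_FIELDS) + '">'
    ]
    lines = _vcf_header(cohort, info_lines)
    for v in sorted(cohort.variants, key=variant_sort_key):
        pc = parse_protein_change(v.aa_change)
        values = {
            "Allele": vep_allele(v.ref, v.alt),
            "Consequence": _vep_consequence(v),
            "IMPACT": "MODERATE",
            "SYMBOL": v.gene or "",
            "Protein_position": str(pc[0]) if pc else "",
            "Amino_acids": f"{pc[1]}/{pc[2]}" if pc else "",
            "HGVSc": v.cdna_change or "",
            "SIFT": _vep_pred(v, "sift", "sift"),
            "PolyPhen": _vep_pred(v, "polyphen2_hdiv", "polyphen"),
            "MutationTaster_pred": _vep_pred(v, "mutationtaster", "letter"),
            "LRT_pred": _vep_pred(v, "lrt", "letter"),
            "ClinVar_CLNSIG": _csq_escape(v.clinvar_sig or ""),
            "ClinVar_CLNREVSTAT": _csq_escape(v.clinvar_status or ""),
            "DOMAINS": _csq_escape(v.domain_annotation or ""),
            "RepeatRegion": "1" if v.repeat_region else "",
            "ada_score": _fmt(v.splice_pred) if v.splice_pred is not None else "",
            "gnomAD_nhomalt": str(v.hom_count) if v.hom_count is not None else "",
        }
        for csq_name, canonical in _CSQ_FREQ.items():
            freq = v.pop_freqs.get(canonical)
            values[csq_name] = repr(freq) if freq is not None else ""
        csq = "|".join(values[f] for f in _CSQ_FIELDS)
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", f"CSQ={csq}", "GT"]
        row += [_GT_TEXT[v.genotypes[s]] for s in cohort.samples]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = ["sample\ttrio_id\trole\taffected"]
    for e in pedigree.entries:
        lines.append(f"{e.sample}\t{e.trio_id}\t{e.role}\t{int(e.affected)}")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_cohort(
    spec: FixtureSpec | None = None,
    outdir: str | Path = ".",
    tables: ReferenceTables | None = None,
    config: EngineConfig | None = None,
) -> FixtureResult:
    """Write the ANNOVAR-TSV, ANNOVAR-VCF and VEP-VCF renderings of one
    synthetic cohort (plus its pedigree) and return the ground truth.

    Output is byte-identical for identical spec and seed.
    """
    spec = spec if spec is not None else default_spec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, pedigree, truth = build_cohort(spec, tables, config)
    paths = {
        "annovar_tsv": outdir / "cohort.annovar.tsv",
        "annovar_vcf": outdir / "cohort.annovar.vcf",
        "vep_vcf": outdir / "cohort.vep.vcf",
    }
    write_annovar_tsv(cohort, paths["annovar_tsv"])
    write_annovar_vcf(cohort, paths["annovar_vcf"])
    write_vep_vcf(cohort, paths["vep_vcf"])
    if pedigree is not None:
        paths["pedigree"] = outdir / "pedigree.tsv"
        write_pedigree(pedigree, paths["pedigree"])
    return FixtureResult(cohort=cohort, pedigree=pedigree, truth=truth, paths=paths)


# --- randomized mode (property tests) -----------------------------------------------

_RANDOM_GENES = (
    "BRCA2", "TP53", "SCN1A", "MLH1", "PTEN", "CFTR", "TTN", "ACTB", "MYH7",
    "MUC16", "ALDH2", "KRAS", "GENE1", "GENE2",
)
_RANDOM_EXONIC = (
    "nonsynonymous SNV", "synonymous SNV", "stopgain", "frameshift deletion",
    "nonframeshift insertion", "nonframeshift deletion", "stoploss", None,
)


def random_variant(rng: random.Random, index: int = 0) -> AnnotatedVariant:
    """One unstructured random variant (no genotypes) for fuzzing the engine."""
    freqs = {}
    for label in ("exac_all", "gnomad_exome_all"):
        if rng.random() < 0.6:
            freqs[label] = round(rng.random() ** 4, 8)  # skewed toward rare
    preds = {}
    for label in ("sift", "polyphen2_hdiv", "mutationtaster", "lrt"):
        if rng.random() < 0.7:
            preds[label] = rng.choice(("deleterious", "tolerated"))
    aa = None
    if rng.random() < 0.3:
        aa = f"p.R{rng.randint(1, 500)}{rng.choice('HLCWQ')}"
    return AnnotatedVariant(
        chrom=str(rng.randint(1, 22)),
        pos=10_000 + index,
        ref="A",
        alt=rng.choice(("C", "G", "T", "ACC")),
        gene=rng.choice(_RANDOM_GENES),
        func_region=rng.choice(("exonic", "splicing", "intronic")),
        exonic_func=rng.choice(_RANDOM_EXONIC),
        aa_change=aa,
        pop_freqs=freqs,
        predictor_calls=preds,
        clinvar_sig=rng.choice((None, "Pathogenic", "Benign", "Likely_benign")),
        clinvar_status=rng.choice(
            (None, _ASSERTED_STATUS, _NO_ASSERTION_STATUS, _EXPERT_STATUS)
        ),
        domain_annotation=rng.choice((None, "Ion transport domain", "Olfactory receptor")),
        repeat_region=rng.choice((None, True, False)),
        splice_pred=rng.choice((None, 0.1, 0.9)),
        hom_count=rng.choice((None, 0, 3)),
    )
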
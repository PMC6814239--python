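"""Automatic assignment of ACMG/AMP evidence criteria to annotated variants.

Nineteen criteria are derivable from a well-annotated variant file plus small
reference tables: PVS1, PS1, PS3, PM1, PM2, PM4, PM5, PP2, PP3, PP5, BA1,
BS1, BS2, BS3, BP1, BP3, BP4, BP6 and BP7.  PS2 (trio de novo) and PS4
(cohort enrichment) are assigned by the :mod:`exotier.trio` and
:mod:`exotier.enrichment` modules.  Criteria whose evidence an annotated file
cannot carry (segregation, phase, phenotype specificity) are never assigned.

Every predicate is an independent function of ``(variant, tables, config)``
returning a justification string when the criterion fires, so each one can be
unit-tested in isolation.  Assignment is deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path

from .exceptions import ConfigError
from .models import AnnotatedVariant, CriteriaSet, parse_protein_change

# consequence vocabularies (ANNOVAR spelling is the canonical one)
LOF_CONSEQUENCES = frozenset(
    {"stopgain", "frameshift insertion", "frameshift deletion", "startloss"}
)
INFRAME_CONSEQUENCES = frozenset(
    {"nonframeshift insertion", "nonframeshift deletion"}
)
MISSENSE = "nonsynonymous SNV"
SYNONYMOUS = "synonymous SNV"

# ClinVar review statuses carrying an assertion (strong evidence) vs not.
_ASSERTION_BACKED = ("practice guideline", "reviewed by expert panel", "criteria provided")
_PATHOGENIC_WORD = "pathogenic"
_BENIGN_WORD = "benign"


@dataclass
class EngineConfig:
    """Tunable cut-offs for the criteria predicates.

    rare_threshold
        population AF below which a variant counts as absent/rare (PM2).
    bs1_threshold
        population AF above which BS1 fires (when BA1 does not).
    ba1_threshold
        stand-alone benign frequency cut-off.
    bs2_hom_count
        BS2 fires when the reported homozygote count exceeds this.
    pp3_fraction / bp4_fraction
        fraction of available in-silico predictors that must agree.
    min_predictors
        minimum number of non-missing predictor calls for PP3/BP4.
    splice_threshold
        splice-impact score below which a synonymous variant keeps BP7.
    """

    rare_threshold: float = 1e-4
    bs1_threshold: float = 0.01
    ba1_threshold: float = 0.05
    bs2_hom_count: int = 0
    pp3_fraction: float = 0.5
    bp4_fraction: float = 0.5
    min_predictors: int = 2
    splice_threshold: float = 0.6

    @classmethod
    def from_file(cls, path: str | Path) -> "EngineConfig":
        """Read ``key=value`` overrides; unknown keys are rejected."""
        known = {f.name: f.type for f in dc_fields(cls)}
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"expected key=value, got {line!r}")
            key, value = (t.strip() for t in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"unknown configuration key {key!r}")
            kwargs[key] = int(value) if key in ("bs2_hom_count", "min_predictors") else float(value)
        return cls(**kwargs)


def _read_gene_list(path) -> frozenset[str]:
    lines = Path(path).read_text().splitlines()
    return frozenset(
        line.strip().upper() for line in lines if line.strip() and not line.startswith("#")
    )


def _read_aa_table(path) -> dict[tuple[str, int], list[tuple[str, str, str | None]]]:
    table: dict[tuple[str, int], list[tuple[str, str, str | None]]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header = rows[0]
    idx = {name: header.index(name) for name in ("gene", "protein_pos", "ref_aa", "alt_aa")}
    cdna_idx = header.index("cdna_change") if "cdna_change" in header else None
    for row in rows[1:]:
        gene = row[idx["gene"]].upper()
        pos = int(row[idx["protein_pos"]])
        cdna = None
        if cdna_idx is not None and row[cdna_idx] not in (".", ""):
            cdna = row[cdna_idx]
        table.setdefault((gene, pos), []).append((row[idx["ref_aa"]], row[idx["alt_aa"]], cdna))
    return table


def _data_path(name: str):
    return resources.files("exotier").joinpath("data", name)


@dataclass
class ReferenceTables:
    """Bundled gene/domain lookup tables; every table may be empty, in which
    case the criteria that need it simply never fire."""

    lof_intolerant_genes: frozenset[str] = frozenset()
    missense_constrained_genes: frozenset[str] = frozenset()
    truncating_mechanism_genes: frozenset[str] = frozenset()
    pathogenic_aa_changes: dict[tuple[str, int], list[tuple[str, str, str | None]]] = field(
        default_factory=dict
    )
    benign_domains: frozenset[str] = frozenset()

    @classmethod
    def load_default(cls) -> "ReferenceTables":
        """Load the bundled synthetic stand-in tables shipped with the package."""
        return cls(
            lof_intolerant_genes=_read_gene_list(_data_path("lof_intolerant_genes.synthetic.txt")),
            missense_constrained_genes=_read_gene_list(
                _data_path("missense_constrained_genes.synthetic.txt")
            ),
            truncating_mechanism_genes=_read_gene_list(
                _data_path("truncating_mechanism_genes.synthetic.txt")
            ),
            pathogenic_aa_changes=_read_aa_table(_data_path("pathogenic_aa_changes.synthetic.tsv")),
            benign_domains=frozenset(
                d.lower() for d in _read_gene_list(_data_path("benign_domains.synthetic.txt"))
            ),
        )


def load_flags_genes() -> frozenset[str]:
    """Bundled FLAGS snapshot (frequently mutated genes in public exomes)."""
    return _read_gene_list(_data_path("flags_genes.synthetic.txt"))


# --- helpers ---------------------------------------------------------------------


def _gene(v: AnnotatedVariant) -> str:
    return (v.gene or "").upper()


def _sig_is(v: AnnotatedVariant, word: str) -> bool:
    if not v.clinvar_sig:
        return False
    sig = v.clinvar_sig.lower()
    return word in sig and "conflicting" not in sig


def _status_assertion_backed(v: AnnotatedVariant) -> bool:
    if not v.clinvar_status:
        return False
    status = v.clinvar_status.lower()
    if "no assertion" in status:
        return False
    return any(tag in status for tag in _ASSERTION_BACKED)


def _predictor_fractions(v: AnnotatedVariant) -> tuple[int, int, int]:
    """(available, deleterious, tolerated) among non-missing predictor calls."""
    calls = [c for c in v.predictor_calls.values() if c in ("deleterious", "tolerated")]
    return (
        len(calls),
        sum(1 for c in calls if c == "deleterious"),
        sum(1 for c in calls if c == "tolerated"),
    )


def _domain_is_benign(domain: str, tables: ReferenceTables) -> bool:
    low = domain.lower()
    return any(b in low for b in tables.benign_domains)


# --- criterion predicates ----------------------------------------------------------


def pvs1(v, tables, config):
    if _gene(v) not in tables.lof_intolerant_genes:
        return None
    if v.exonic_func in LOF_CONSEQUENCES:
        return f"{v.exonic_func} in LOF-intolerant gene {v.gene}"
    if v.func_region == "splicing":
        return f"splice-site variant in LOF-intolerant gene {v.gene}"
    return None


def ps1(v, tables, config):
    pc = parse_protein_change(v.aa_change)
    if pc is None:
        return None
    pos, ref_aa, alt_aa = pc
    for known_ref, known_alt, known_cdna in tables.pathogenic_aa_changes.get((_gene(v), pos), []):
        if known_ref != ref_aa or known_alt != alt_aa:
            continue
        # same residue substitution; only a *different* nucleotide change
        # counts -- an identical cDNA change is the known variant itself.
        if known_cdna is not None and v.cdna_change is not None and known_cdna == v.cdna_change:
            continue
        return f"p.{ref_aa}{pos}{alt_aa} known pathogenic via different nucleotide change"
    return None


def ps3(v, tables, config):
    if _sig_is(v, _PATHOGENIC_WORD) and _status_assertion_backed(v):
        return f"ClinVar pathogenic with assertion-backed review ({v.clinvar_status})"
    return None


def pm1(v, tables, config):
    if v.exonic_func != MISSENSE or not v.domain_annotation:
        return None
    if _domain_is_benign(v.domain_annotation, tables):
        return None
    return f"missense in functional domain {v.domain_annotation}"


def pm2(v, tables, config):
    high = [f"{k}={f}" for k, f in v.pop_freqs.items() if f >= config.rare_threshold]
    if high:
        return None
    return "absent from or rare in all population databases"


def pm4(v, tables, config):
    if v.exonic_func in INFRAME_CONSEQUENCES | {"stoploss"} and v.repeat_region is not True:
        return f"protein-length change ({v.exonic_func}) outside repeat region"
    return None


def pm5(v, tables, config):
    if ps1(v, tables, config) is not None:
        return None
    pc = parse_protein_change(v.aa_change)
    if pc is None:
        return None
    pos, ref_aa, alt_aa = pc
    for known_ref, known_alt, _ in tables.pathogenic_aa_changes.get((_gene(v), pos), []):
        if known_ref == ref_aa and known_alt != alt_aa:
            return (
                f"novel missense p.{ref_aa}{pos}{alt_aa} at residue with known "
                f"pathogenic change p.{known_ref}{pos}{known_alt}"
            )
    return None


def pp2(v, tables, config):
    if v.exonic_func == MISSENSE and _gene(v) in tables.missense_constrained_genes:
        return f"missense in missense-constrained gene {v.gene}"
    return None


def pp3(v, tables, config):
    available, deleterious, _ = _predictor_fractions(v)
    if available >= config.min_predictors and deleterious / available >= config.pp3_fraction:
        return f"{deleterious}/{available} in-silico predictors deleterious"
    return None


def pp5(v, tables, config):
    if _sig_is(v, _PATHOGENIC_WORD) and not _status_assertion_backed(v):
        return "ClinVar pathogenic without assertion criteria"
    return None


def ba1(v, tables, config):
    for label, f in v.pop_freqs.items():
        if f > config.ba1_threshold:
            return f"{label}={f} > {config.ba1_threshold}"
    return None


def bs1(v, tables, config):
    if ba1(v, tables, config) is not None:
        return None
    freq = v.max_pop_freq
    if freq is not None and freq > config.bs1_threshold:
        return f"max population AF {freq} > {config.bs1_threshold}"
    return None


def bs2(v, tables, config):
    if v.hom_count is not None and v.hom_count > config.bs2_hom_count:
        return f"{v.hom_count} reported homozygotes"
    return None


def bs3(v, tables, config):
    if _sig_is(v, _BENIGN_WORD) and _status_assertion_backed(v):
        return f"ClinVar benign with assertion-backed review ({v.clinvar_status})"
    return None


def bp1(v, tables, config):
    if v.exonic_func == MISSENSE and _gene(v) in tables.truncating_mechanism_genes:
        return f"missense in truncating-mechanism gene {v.gene}"
    return None


def bp3(v, tables, config):
    if (
        v.exonic_func in INFRAME_CONSEQUENCES
        and v.repeat_region is True
        and not v.domain_annotation
    ):
        return "in-frame indel in repeat region without domain annotation"
    return None


def bp4(v, tables, config):
    available, _, tolerated = _predictor_fractions(v)
    if available >= config.min_predictors and tolerated / available >= config.bp4_fraction:
        return f"{tolerated}/{available} in-silico predictors benign"
    return None


def bp6(v, tables, config):
    if _sig_is(v, _BENIGN_WORD) and not _status_assertion_backed(v):
        return "ClinVar benign without assertion criteria"
    return None


def bp7(v, tables, config):
    if v.exonic_func != SYNONYMOUS:
        return None
    if v.splice_pred is None or v.splice_pred < config.splice_threshold:
        return "synonymous without predicted splice impact"
    return None


#: predicate registry, in assignment order (PS1 before PM5, BA1 before BS1).
PREDICATES = {
    "PVS1": pvs1,
    "PS1": ps1,
    "PS3": ps3,
    "PM1": pm1,
    "PM2": pm2,
    "PM4": pm4,
    "PM5": pm5,
    "PP2": pp2,
    "PP3": pp3,
    "PP5": pp5,
    "BA1": ba1,
    "BS1": bs1,
    "BS2": bs2,
    "BS3": bs3,
    "BP1": bp1,
    "BP3": bp3,
    "BP4": bp4,
    "BP6": bp6,
    "BP7": bp7,
}


def assign_criteria(
    v: AnnotatedVariant,
    tables: ReferenceTables | None = None,
    config: EngineConfig | None = None,
) -> CriteriaSet:
    """Evaluate every automatically derivable criterion on one variant.

    Missing annotations never raise; they simply prevent the criteria that
    need them.  The result is deterministic in the variant and the tables.
    """
    tables = tables if tables is not None else ReferenceTables.load_default()
    config = config if config is not None else EngineConfig()
    result = CriteriaSet()
    for label, predicate in PREDICATES.items():
        note = predicate(v, tables, config)
        if note is not None:
            result.add(label, note)
    return result
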
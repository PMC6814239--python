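"""Readers and writers for annotated variant files.

Three input layouts feed the same uniform variant model:

* ANNOVAR multianno-style tab/comma tables (one row per allele, per-sample
  genotype columns detected automatically),
* VCFs carrying ANNOVAR ``key=value`` INFO annotations,
* VCFs carrying VEP ``CSQ`` annotations (field list taken from the header).

Column names are normalized through an alias table covering the common
dialect spellings; anything unrecognized is preserved as passthrough
metadata.  The missing-value sentinels ``.``, empty string and ``NA`` all map
to absent.  Multi-allelic VCF records are decomposed into one record per
alternate allele with genotypes re-expressed against that allele; a genotype
containing any missing allele decodes as missing (never as a carrier).
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .exceptions import FormatError, InputError
from .models import (
    AnnotatedVariant,
    Cohort,
    Genotype,
    chrom_sort_key,
    parse_cdna_change,
)

MISSING_SENTINELS = {".", "", "na", "nan", "n/a"}

_GT_RE = re.compile(r"^(\d+|\.)[/|](\d+|\.)$")
_GT_WORD_RE = re.compile(r"^(het|hom|hom_alt|hom_ref|wt|ref)$", re.IGNORECASE)


def is_missing(value) -> bool:
    return value is None or str(value).strip().lower() in MISSING_SENTINELS


# --- column-name normalization ------------------------------------------------------

#: canonical scalar field -> known dialect spellings (matched case-insensitively)
FIELD_ALIASES: dict[str, tuple[str, ...]] = {
    "chrom": ("Chr", "CHROM", "#CHROM", "Chromosome"),
    "pos": ("Start", "POS", "Position"),
    "ref": ("Ref", "REF", "Reference"),
    "alt": ("Alt", "ALT", "Alternate"),
    "gene": ("Gene.refGene", "Gene.refGeneWithVer", "Gene.ensGene", "Gene.knownGene",
             "SYMBOL", "Gene_symbol"),
    "func_region": ("Func.refGene", "Func.refGeneWithVer", "Func.ensGene", "Func.knownGene"),
    "exonic_func": ("ExonicFunc.refGene", "ExonicFunc.refGeneWithVer", "ExonicFunc.ensGene",
                    "ExonicFunc.knownGene"),
    "aa_change": ("AAChange.refGene", "AAChange.refGeneWithVer", "AAChange.ensGene",
                  "AAChange.knownGene", "HGVSp"),
    "cdna_change": ("HGVSc",),
    "clinvar_sig": ("CLNSIG", "CLINSIG", "ClinVar_CLNSIG", "CLIN_SIG", "clinvar_sig"),
    "clinvar_status": ("CLNREVSTAT", "ClinVar_CLNREVSTAT", "clinvar_review_status"),
    "domain_annotation": ("Interpro_domain", "DOMAINS", "Domain"),
    "repeat_region": ("genomicSuperDups", "rmsk", "RepeatMasker", "RepeatRegion", "Repeat"),
    "splice_pred": ("dbscSNV_ADA_SCORE", "dbscSNV_RF_SCORE", "ada_score", "rf_score"),
    "hom_count": ("gnomAD_exome_nhomalt", "gnomAD_nhomalt", "nhomalt", "Hom"),
}

#: canonical population-frequency label -> dialect spellings
FREQ_ALIASES: dict[str, tuple[str, ...]] = {
    "exac_all": ("ExAC_ALL", "ExAC_AF"),
    "gnomad_exome_all": ("gnomAD_exome_ALL", "gnomAD_exome_AF", "gnomADe_AF", "AF_exome"),
    "gnomad_genome_all": ("gnomAD_genome_ALL", "gnomAD_genome_AF", "gnomADg_AF", "AF_genome"),
    "gnomad_af": ("gnomAD_AF",),
    "thousand_genomes": ("1000g2015aug_all", "1000G_ALL", "1000Gp3_AF", "AF_1000G"),
    "esp6500": ("esp6500siv2_all", "ESP_AF"),
}

#: canonical in-silico predictor label -> dialect spellings
PREDICTOR_ALIASES: dict[str, tuple[str, ...]] = {
    "sift": ("SIFT_pred", "SIFT"),
    "polyphen2_hdiv": ("Polyphen2_HDIV_pred",),
    "polyphen2_hvar": ("Polyphen2_HVAR_pred", "PolyPhen"),
    "mutationtaster": ("MutationTaster_pred",),
    "lrt": ("LRT_pred",),
    "fathmm": ("FATHMM_pred",),
    "provean": ("PROVEAN_pred",),
    "metasvm": ("MetaSVM_pred",),
    "metalr": ("MetaLR_pred",),
}

#: in the VEP CSQ field list, a bare ``AF`` is the 1000 Genomes frequency;
#: elsewhere (VCF INFO) it is the cohort allele frequency and is passthrough.
_CSQ_ONLY_FREQ = {"af": "thousand_genomes"}

_SPACED_FIELDS = {"func_region", "exonic_func", "clinvar_sig", "clinvar_status",
                  "domain_annotation"}


def _build_alias_lookup(csq: bool) -> dict[str, tuple[str, str]]:
    lookup: dict[str, tuple[str, str]] = {}
    for canonical, spellings in FIELD_ALIASES.items():
        for s in spellings:
            lookup[s.lower()] = ("field", canonical)
    for canonical, spellings in FREQ_ALIASES.items():
        for s in spellings:
            lookup[s.lower()] = ("freq", canonical)
        lookup[canonical] = ("freq", canonical)
    for canonical, spellings in PREDICTOR_ALIASES.items():
        for s in spellings:
            lookup[s.lower()] = ("pred", canonical)
    if csq:
        for s, canonical in _CSQ_ONLY_FREQ.items():
            lookup[s] = ("freq", canonical)
    return lookup


_LOOKUP_PLAIN = _build_alias_lookup(csq=False)
_LOOKUP_CSQ = _build_alias_lookup(csq=True)

_ANNOVAR_ESCAPES = (("\\x3b", ";"), ("\\x3d", "="), ("\\x2c", ","), ("\\x20", " "))


def _normalize_spaced(value: str) -> str:
    """Undo VCF-safe encodings of free-text annotation values."""
    for code, char in _ANNOVAR_ESCAPES:
        value = value.replace(code, char)
    value = value.replace("&", ", ")
    value = value.replace("_", " ")
    return value.strip()


def decode_predictor_call(value: str) -> str:
    """Map a predictor's categorical output to deleterious/tolerated/unknown."""
    v = value.strip()
    if not v or v.lower() in MISSING_SENTINELS:
        return "unknown"
    low = v.lower()
    if low.startswith(("deleterious", "damaging", "probably_damaging", "possibly_damaging",
                       "probably damaging", "possibly damaging")):
        return "deleterious"
    if low.startswith(("tolerated", "benign", "neutral")):
        return "tolerated"
    letter = v[0].upper()
    if letter in ("D", "A", "P", "H"):  # damaging / disease-causing / possibly / high
        return "deleterious"
    if letter in ("T", "B", "N"):  # tolerated / benign / neutral-polymorphism
        return "tolerated"
    return "unknown"


def _apply_annotation(kind: str, canonical: str, raw: str, fields: dict, spaced: bool) -> None:
    """Set one normalized annotation value on the draft variant dict."""
    if is_missing(raw):
        return
    value = str(raw).strip()
    if kind == "freq":
        try:
            fields.setdefault("pop_freqs", {})[canonical] = float(value)
        except ValueError:
            pass
        return
    if kind == "pred":
        call = decode_predictor_call(value)
        if call != "unknown":
            fields.setdefault("predictor_calls", {})[canonical] = call
        return
    if canonical == "splice_pred":
        try:
            fields[canonical] = float(value)
        except ValueError:
            pass
    elif canonical == "hom_count":
        try:
            fields[canonical] = int(float(value))
        except ValueError:
            pass
    elif canonical == "repeat_region":
        fields[canonical] = value.lower() not in ("0", "false", "no")
    elif canonical == "cdna_change":
        fields[canonical] = parse_cdna_change(value) or value
    elif canonical in _SPACED_FIELDS:
        fields[canonical] = _normalize_spaced(value) if spaced else value
    elif canonical == "aa_change":
        fields[canonical] = value
        cdna = parse_cdna_change(value)
        if cdna and "cdna_change" not in fields:
            fields["cdna_change"] = cdna
    else:
        fields[canonical] = value


# --- ANNOVAR tables ------------------------------------------------------------------


def _looks_like_genotypes(values: list[str]) -> bool:
    seen = [v for v in values if not is_missing(v)]
    if not seen:
        return False
    return all(_GT_RE.match(v.strip()) or _GT_WORD_RE.match(v.strip()) for v in seen)


def read_annovar_table(path: str | Path, delimiter: str | None = None) -> Cohort:
    """Read an ANNOVAR multianno-style table (TSV or CSV) into a cohort.

    ``delimiter`` defaults to ``,`` for ``.csv`` files and tab otherwise.
    Per-sample genotype columns are detected by content (values like ``0/1``
    or ``het``); unrecognized columns become passthrough metadata.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc

    columns = list(df.columns)
    lower_to_col = {c.lower(): c for c in columns}
    coords: dict[str, str] = {}
    for canonical in ("chrom", "pos", "ref", "alt"):
        for spelling in FIELD_ALIASES[canonical]:
            if spelling.lower() in lower_to_col:
                coords[canonical] = lower_to_col[spelling.lower()]
                break
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in coords]
    if missing:
        raise FormatError(
            f"{path} has no recognizable coordinate columns for: {', '.join(missing)} "
            f"(expected spellings like "
            f"{', '.join('/'.join(FIELD_ALIASES[m][:2]) for m in missing)})"
        )

    annotation_cols: dict[str, tuple[str, str]] = {}
    other_cols: list[str] = []
    for col in columns:
        if col in coords.values():
            continue
        hit = _LOOKUP_PLAIN.get(col.lower())
        if hit:
            annotation_cols[col] = hit
        else:
            other_cols.append(col)

    sample_cols = [c for c in other_cols if _looks_like_genotypes(df[c].tolist())]
    passthrough_cols = [c for c in other_cols if c not in sample_cols]

    variants = []
    for row in df.itertuples(index=False):
        record = dict(zip(columns, row))
        alt = str(record[coords["alt"]]).strip()
        if "," in alt:
            raise FormatError(
                f"{path}: multi-allelic alt {alt!r} in a table row; ANNOVAR tables "
                "are expected to be one allele per row"
            )
        fields: dict = {
            "chrom": str(record[coords["chrom"]]).strip(),
            "pos": int(float(record[coords["pos"]])),
            "ref": str(record[coords["ref"]]).strip(),
            "alt": alt,
        }
        for col, (kind, canonical) in annotation_cols.items():
            _apply_annotation(kind, canonical, record[col], fields, spaced=True)
        fields["genotypes"] = {
            s: Genotype.from_string(str(record[s])) if not is_missing(record[s])
            else Genotype.MISSING
            for s in sample_cols
        }
        fields["passthrough"] = {
            c: "" if is_missing(record[c]) else str(record[c]) for c in passthrough_cols
        }
        variants.append(AnnotatedVariant(**fields))
    return Cohort(samples=sample_cols, variants=variants)


# --- VCF dialects --------------------------------------------------------------------


def vep_allele(ref: str, alt: str) -> str:
    """VEP's minimal allele spelling for a REF/ALT pair."""
    if len(ref) == 1 and len(alt) == 1:
        return alt
    if ref[0] == alt[0]:
        return alt[1:] if len(alt) > 1 else "-"
    return alt


#: VEP SO consequence term -> (func_region, exonic_func template)
VEP_CONSEQUENCE_MAP: dict[str, tuple[str, str | None]] = {
    "stop_gained": ("exonic", "stopgain"),
    "frameshift_variant": ("exonic", "frameshift"),
    "missense_variant": ("exonic", "nonsynonymous SNV"),
    "synonymous_variant": ("exonic", "synonymous SNV"),
    "inframe_insertion": ("exonic", "nonframeshift insertion"),
    "inframe_deletion": ("exonic", "nonframeshift deletion"),
    "stop_lost": ("exonic", "stoploss"),
    "start_lost": ("exonic", "startloss"),
    "splice_donor_variant": ("splicing", None),
    "splice_acceptor_variant": ("splicing", None),
    "intron_variant": ("intronic", None),
    "5_prime_UTR_variant": ("UTR5", None),
    "3_prime_UTR_variant": ("UTR3", None),
    "upstream_gene_variant": ("upstream", None),
    "downstream_gene_variant": ("downstream", None),
    "intergenic_variant": ("intergenic", None),
}


def _csq_format(vcf: VCF, path: Path) -> list[str]:
    try:
        header = vcf.get_header_type("CSQ")
    except KeyError as exc:
        raise FormatError(
            f"{path}: dialect 'vep' requires a CSQ INFO header with a Format list"
        ) from exc
    description = header.get("Description", "")
    if "Format:" not in description:
        raise FormatError(f"{path}: CSQ header lacks a 'Format:' field list")
    fmt = description.split("Format:", 1)[1].strip().strip('"')
    return [f.strip() for f in fmt.split("|")]


def _apply_csq(entry: dict[str, str], ref: str, alt: str, fields: dict) -> None:
    consequence = entry.get("Consequence", "")
    for term in consequence.split("&"):
        hit = VEP_CONSEQUENCE_MAP.get(term.strip())
        if hit is None:
            continue
        func_region, exonic = hit
        fields.setdefault("func_region", func_region)
        if exonic == "frameshift":
            exonic = "frameshift insertion" if len(alt) > len(ref) else "frameshift deletion"
        if exonic is not None:
            fields.setdefault("exonic_func", exonic)
        break
    pos_txt = entry.get("Protein_position", "")
    aas = entry.get("Amino_acids", "")
    if not is_missing(pos_txt) and "/" in aas:
        ref_aa, alt_aa = aas.split("/", 1)
        residue = pos_txt.split("-")[0].split("/")[0]
        if residue.isdigit() and ref_aa and alt_aa:
            fields.setdefault("aa_change", f"p.{ref_aa}{residue}{alt_aa}")
    for name, raw in entry.items():
        hit = _LOOKUP_CSQ.get(name.lower())
        if hit is None:
            if not is_missing(raw) and name not in ("Allele", "Consequence",
                                                    "Protein_position", "Amino_acids"):
                fields.setdefault("passthrough", {}).setdefault(f"CSQ_{name}", raw)
            continue
        kind, canonical = hit
        if canonical == "aa_change" and "aa_change" in fields:
            continue
        _apply_annotation(kind, canonical, raw, fields, spaced=True)


def read_annotated_vcf(path: str | Path, dialect: str = "annovar") -> Cohort:
    """Read an annotated (possibly bgzipped) VCF into a cohort.

    ``dialect`` is ``annovar`` (key=value INFO annotations) or ``vep`` (CSQ
    INFO field).  Multi-allelic sites are decomposed; per-sample GT fields are
    parsed into genotypes, and non-diploid calls decode as missing with a
    record-level warning.
    """
    path = Path(path)
    if dialect not in ("annovar", "vep"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise InputError(f"no such file: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    csq_fields = _csq_format(vcf, path) if dialect == "vep" else None

    variants = []
    for record in vcf:
        alts = record.ALT
        raw_gts = record.genotypes if samples else []
        allele_calls: list[list[int]] = []
        for sample, gt in zip(samples, raw_gts):
            alleles = list(gt[:-1])  # last element is the phasing flag
            if len(alleles) != 2:
                warnings.warn(
                    f"non-diploid genotype for {sample} at {record.CHROM}:{record.POS}; "
                    "treated as missing",
                    stacklevel=2,
                )
                alleles = [-1, -1]
            allele_calls.append(alleles)
        info_pairs = dict(record.INFO)
        for alt_idx, alt in enumerate(alts, start=1):
            fields: dict = {
                "chrom": record.CHROM,
                "pos": record.POS,
                "ref": record.REF,
                "alt": alt,
            }
            if dialect == "vep":
                raw_csq = info_pairs.get("CSQ")
                if raw_csq:
                    want = vep_allele(record.REF, alt)
                    for chunk in str(raw_csq).split(","):
                        entry = dict(zip(csq_fields, chunk.split("|")))
                        if entry.get("Allele", "") in (want, alt):
                            _apply_csq(entry, record.REF, alt, fields)
                            break
                for key, value in info_pairs.items():
                    if key != "CSQ":
                        fields.setdefault("passthrough", {})[key] = str(value)
            else:
                for key, value in info_pairs.items():
                    value = True if value is None else value
                    hit = _LOOKUP_PLAIN.get(key.lower())
                    if hit is None:
                        fields.setdefault("passthrough", {})[key] = str(value)
                        continue
                    kind, canonical = hit
                    raw = str(value)
                    if kind == "freq" and raw.count(",") == len(alts) - 1 and len(alts) > 1:
                        raw = raw.split(",")[alt_idx - 1]
                    _apply_annotation(kind, canonical, raw, fields, spaced=True)
            fields["genotypes"] = {
                s: Genotype.from_allele_indices(calls, alt_index=alt_idx)
                for s, calls in zip(samples, allele_calls)
            }
            variants.append(AnnotatedVariant(**fields))
    return Cohort(samples=samples, variants=variants)


# --- report writing ------------------------------------------------------------------

#: leading column order of every report
REPORT_CORE_COLUMNS = [
    "Chr", "Pos", "Ref", "Alt", "Gene",
    "ACMG_criteria", "ACMG_class", "Posterior_probability", "Probability_verdict",
    "De_novo_trios",
    "Cohort_carriers", "Cohort_noncarriers",
    "Control_carriers", "Control_noncarriers", "Odds_ratio", "P_value", "PS4",
]


def sort_report(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: natural chromosome, then pos, ref, alt."""
    if df.empty or "Chr" not in df.columns:
        return df
    key = df.apply(
        lambda r: (*chrom_sort_key(str(r["Chr"])), int(r["Pos"]), str(r["Ref"]), str(r["Alt"])),
        axis=1,
    )
    return df.iloc[key.argsort(kind="stable")].reset_index(drop=True)


def order_columns(df: pd.DataFrame) -> pd.DataFrame:
    lead = [c for c in REPORT_CORE_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    return df[lead + rest]


def write_report(df: pd.DataFrame, path: str | Path, file_format: str | None = None) -> None:
    """Write one report table as TSV, CSV or a single-sheet workbook.

    Columns are reordered (coordinates, gene, criteria, class, posterior,
    enrichment fields, then passthrough annotations) and rows sorted by
    (chrom, pos, ref, alt).
    """
    path = Path(path)
    if file_format is None:
        file_format = {".csv": "csv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "tsv")
    out = order_columns(sort_report(df.copy()))
    try:
        if file_format == "tsv":
            out.to_csv(path, sep="\t", index=False)
        elif file_format == "csv":
            out.to_csv(path, index=False)
        elif file_format == "xlsx":
            out.to_excel(path, index=False, sheet_name="main")
        else:
            raise ValueError(f"unknown report format {file_format!r}")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def write_workbook(sheets: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write several report tables as one multi-sheet workbook."""
    path = Path(path)
    try:
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, df in sheets.items():
                ordered = order_columns(sort_report(df.copy())) if "Chr" in df.columns else df
                ordered.to_excel(writer, index=False, sheet_name=name[:31])
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
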
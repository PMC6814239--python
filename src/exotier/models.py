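"""Core domain model: genotypes, annotated variants, cohorts and criteria sets.

A cohort is a list of bi-allelic :class:`AnnotatedVariant` records sharing one
ordered sample list.  Multi-allelic input records are decomposed on read, so
``alt`` is always a single allele.  Annotation fields use one uniform,
normalized vocabulary regardless of which annotation tool produced the input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable


class Genotype(Enum):
    """Diploid genotype of one sample with respect to one alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        """A carrier holds at least one copy of the alternate allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)

    @classmethod
    def from_allele_indices(cls, alleles: Iterable[int], alt_index: int = 1) -> "Genotype":
        """Decode numeric allele indices (VCF style; ``-1`` = missing).

        Non-diploid calls and any call containing a missing allele decode to
        MISSING: partial genotypes such as ``./1`` never count as carriers, so
        cohort carrier counts stay conservative.
        """
        alleles = list(alleles)
        if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
            return cls.MISSING
        n_alt = sum(1 for a in alleles if a == alt_index)
        return (cls.HOM_REF, cls.HET, cls.HOM_ALT)[n_alt]

    @classmethod
    def from_string(cls, gt: str, alt_index: int = 1) -> "Genotype":
        """Decode a textual genotype: ``0/1``, ``1|1``, ``./.`` or a keyword."""
        s = gt.strip()
        word = _GT_WORDS.get(s.lower())
        if word is not None:
            return word
        parts = re.split(r"[/|]", s)
        if len(parts) != 2:
            return cls.MISSING
        try:
            idx = [-1 if p == "." else int(p) for p in parts]
        except ValueError:
            return cls.MISSING
        return cls.from_allele_indices(idx, alt_index)


_GT_WORDS = {
    "het": Genotype.HET,
    "hom": Genotype.HOM_ALT,
    "hom_alt": Genotype.HOM_ALT,
    "hom_ref": Genotype.HOM_REF,
    "wt": Genotype.HOM_REF,
    "ref": Genotype.HOM_REF,
    "missing": Genotype.MISSING,
    "unknown": Genotype.MISSING,
}


@dataclass
class AnnotatedVariant:
    """One bi-allelic variant with normalized annotations and genotypes.

    ``pop_freqs`` maps a canonical population-database label (for example
    ``gnomad_exome_all``) to an allele frequency in [0, 1].
    ``predictor_calls`` maps a canonical in-silico tool label to one of
    ``deleterious`` / ``tolerated`` / ``unknown``.  Unrecognized input columns
    are preserved verbatim in ``passthrough``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    func_region: str | None = None
    exonic_func: str | None = None
    aa_change: str | None = None
    cdna_change: str | None = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, str] = field(default_factory=dict)
    clinvar_sig: str | None = None
    clinvar_status: str | None = None
    domain_annotation: str | None = None
    repeat_region: bool | None = None
    splice_pred: float | None = None
    hom_count: int | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    passthrough: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multi-allelic alt {self.alt!r} at {self.chrom}:{self.pos}; "
                "records must be decomposed on read"
            )
        for label, freq in self.pop_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency {label}={freq} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_pop_freq(self) -> float | None:
        return max(self.pop_freqs.values()) if self.pop_freqs else None

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g.is_carrier]

    def with_samples(self, samples: list[str]) -> "AnnotatedVariant":
        """Copy of this variant restricted to the given samples."""
        return replace(self, genotypes={s: self.genotypes[s] for s in samples})


@dataclass
class Cohort:
    """An ordered sample list plus the variants observed across it."""

    samples: list[str]
    variants: list[AnnotatedVariant]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        expected = list(self.samples)
        for v in self.variants:
            if list(v.genotypes) != expected:
                raise ValueError(
                    f"sample set mismatch at {v.chrom}:{v.pos} "
                    f"({list(v.genotypes)} != {expected})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)


# --- ACMG criteria bookkeeping -------------------------------------------------

PATHOGENIC_VERY_STRONG = ("PVS1",)
PATHOGENIC_STRONG = ("PS1", "PS2", "PS3", "PS4")
PATHOGENIC_MODERATE = ("PM1", "PM2", "PM4", "PM5")
PATHOGENIC_SUPPORTING = ("PP2", "PP3", "PP5")
BENIGN_STANDALONE = ("BA1",)
BENIGN_STRONG = ("BS1", "BS2", "BS3")
BENIGN_SUPPORTING = ("BP1", "BP3", "BP4", "BP6", "BP7")

#: Canonical display / sort order for criteria labels.
CANONICAL_ORDER: tuple[str, ...] = (
    PATHOGENIC_VERY_STRONG
    + PATHOGENIC_STRONG
    + PATHOGENIC_MODERATE
    + PATHOGENIC_SUPPORTING
    + BENIGN_STANDALONE
    + BENIGN_STRONG
    + BENIGN_SUPPORTING
)

#: The closed set of criteria this engine can ever assign.  Criteria needing
#: evidence an annotated file cannot carry (PM3, PM6, PP1, PP4, BS4, BP2, BP5)
#: are deliberately absent.
VALID_CRITERIA = frozenset(CANONICAL_ORDER)

_EXCLUSIONS = (frozenset({"BA1", "PM2"}), frozenset({"BA1", "PS4"}))


@dataclass
class CriteriaSet:
    """The per-variant set of assigned ACMG criteria with justifications."""

    assigned: set[str] = field(default_factory=set)
    evidence_notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unknown = self.assigned - VALID_CRITERIA
        if unknown:
            raise ValueError(f"unknown or unassignable criteria: {sorted(unknown)}")
        for pair in _EXCLUSIONS:
            if pair <= self.assigned:
                raise ValueError(f"mutually exclusive criteria assigned: {sorted(pair)}")

    def add(self, label: str, note: str = "") -> None:
        if label not in VALID_CRITERIA:
            raise ValueError(f"unknown or unassignable criterion: {label}")
        for pair in _EXCLUSIONS:
            other = pair - {label}
            if label in pair and other & self.assigned:
                raise ValueError(
                    f"{label} is mutually exclusive with {sorted(other & self.assigned)}"
                )
        self.assigned.add(label)
        if note:
            self.evidence_notes[label] = note

    def __contains__(self, label: str) -> bool:
        return label in self.assigned

    def sorted(self) -> tuple[str, ...]:
        return tuple(c for c in CANONICAL_ORDER if c in self.assigned)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return ", ".join(self.sorted())


# --- protein / cDNA change parsing ---------------------------------------------

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}

_PCHANGE_RE = re.compile(r"p\.\(?([A-Za-z*]{1,3})(\d+)([A-Za-z*]{1,3})\)?")
_CDNA_RE = re.compile(r"(c\.[0-9_+\-]+[ACGTacgt>delinsdup]+)")


def _aa1(token: str) -> str | None:
    if len(token) == 1 and (token.isupper() or token == "*"):
        return token
    return _AA3TO1.get(token.capitalize())


def parse_protein_change(text: str | None) -> tuple[int, str, str] | None:
    """Extract ``(residue position, ref AA, alt AA)`` from protein notation.

    Accepts bare HGVS-like tokens (``p.R175H``, ``p.Arg175His``) and full
    ANNOVAR AAChange strings (``TP53:NM_000546:exon5:c.524G>A:p.R175H``,
    possibly comma-separated over transcripts; the first parsable token wins).
    """
    if not text:
        return None
    m = _PCHANGE_RE.search(text)
    if not m:
        return None
    ref, alt = _aa1(m.group(1)), _aa1(m.group(3))
    if ref is None or alt is None:
        return None
    return int(m.group(2)), ref, alt


def parse_cdna_change(text: str | None) -> str | None:
    """Extract the first ``c.`` coding-change token, if any."""
    if not text:
        return None
    m = _CDNA_RE.search(text)
    return m.group(1) if m else None


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome ordering: 1..22, X, Y, MT, then others by name."""
    s = str(chrom)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if s.upper() in special:
        return (0, special[s.upper()], "")
    return (1, 0, s)


def variant_sort_key(v: AnnotatedVariant) -> tuple:
    return (*chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)
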
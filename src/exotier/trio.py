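"""Trio de-novo detection (PS2) and healthy-parent removal.

A pedigree is a tab-delimited table with header columns ``sample``,
``trio_id``, ``role`` (father / mother / child) and ``affected`` (0/1).  A
variant is de novo in a trio when the child carries the alternate allele and
both parents are homozygous reference; a missing parental genotype blocks the
call for that trio, avoiding false PS2 from genotype dropout.  PS2 is assigned
when any trio qualifies, and the qualifying trios are reported individually.
Healthy (unaffected) parents are removed from downstream cohort analysis so
they do not dilute carrier frequencies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .exceptions import PedigreeError
from .models import AnnotatedVariant, Cohort, Genotype

ROLES = ("father", "mother", "child")


@dataclass(frozen=True)
class PedigreeEntry:
    sample: str
    trio_id: str
    role: str
    affected: bool


@dataclass
class Pedigree:
    entries: list[PedigreeEntry]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            fieldnames = [f.lower().strip() for f in reader.fieldnames or []]
            required = {"sample", "trio_id", "role", "affected"}
            if not required <= set(fieldnames):
                raise PedigreeError(
                    f"pedigree header must contain {sorted(required)}, got {fieldnames}"
                )
            entries = []
            for row in reader:
                row = {k.lower().strip(): (v or "").strip() for k, v in row.items()}
                role = row["role"].lower()
                if role not in ROLES:
                    raise PedigreeError(f"unknown role {row['role']!r} for {row['sample']!r}")
                if row["affected"] not in ("0", "1"):
                    raise PedigreeError(
                        f"affected must be 0 or 1, got {row['affected']!r} for {row['sample']!r}"
                    )
                entries.append(
                    PedigreeEntry(row["sample"], row["trio_id"], role, row["affected"] == "1")
                )
        return cls(entries)

    def trios(self) -> dict[str, dict[str, PedigreeEntry]]:
        """trio_id -> {role -> entry}; raises unless each trio is complete."""
        grouped: dict[str, dict[str, PedigreeEntry]] = {}
        for e in self.entries:
            roles = grouped.setdefault(e.trio_id, {})
            if e.role in roles:
                raise PedigreeError(f"trio {e.trio_id!r} has duplicate role {e.role!r}")
            roles[e.role] = e
        for trio_id, roles in grouped.items():
            missing = set(ROLES) - set(roles)
            if missing:
                raise PedigreeError(f"trio {trio_id!r} is missing {sorted(missing)}")
        return grouped

    def validate(self, cohort_samples: list[str]) -> None:
        known = set(cohort_samples)
        for e in self.entries:
            if e.sample not in known:
                raise PedigreeError(f"pedigree sample {e.sample!r} absent from the cohort")
        self.trios()

    def healthy_parents(self) -> set[str]:
        return {
            e.sample for e in self.entries if e.role in ("father", "mother") and not e.affected
        }


def detect_de_novo(v: AnnotatedVariant, ped: Pedigree) -> tuple[bool, list[str]]:
    """Per-trio de-novo check; returns (any trio qualifies, qualifying trio ids).

    Trios are independent: the result never depends on their order.
    """
    hits = []
    for trio_id, roles in sorted(ped.trios().items()):
        child = v.genotypes.get(roles["child"].sample, Genotype.MISSING)
        father = v.genotypes.get(roles["father"].sample, Genotype.MISSING)
        mother = v.genotypes.get(roles["mother"].sample, Genotype.MISSING)
        if child.is_carrier and father is Genotype.HOM_REF and mother is Genotype.HOM_REF:
            hits.append(trio_id)
    return bool(hits), hits


def strip_healthy_parents(cohort: Cohort, ped: Pedigree) -> Cohort:
    """Remove unaffected parents from the cohort (idempotent); affected
    parents are retained as ordinary cohort members."""
    drop = ped.healthy_parents()
    kept = [s for s in cohort.samples if s not in drop]
    if kept == cohort.samples:
        return cohort
    return Cohort(samples=kept, variants=[v.with_samples(kept) for v in cohort.variants])
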
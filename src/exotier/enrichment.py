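"""Control-free cohort enrichment and PS4 assignment.

A variant's carrier frequency in the study cohort is tested against the
general population without sequencing controls.  The published control minor
allele frequency MAF_c is converted to integer pseudo-counts by writing it in
normalized scientific notation, MAF_c = y x 10^-x with 1 <= y < 10, and taking

    n_c = ceil(y)            affected control individuals
    N_c = 10^x / 2 - n_c     unaffected control individuals

(so for MAF_c = 3.23e-5: n_c = 4 and N_c = 10^5/2 - 4 = 49996).  The ceiling
deliberately overestimates the control carrier frequency, which makes the
resulting odds ratio smaller than the naive calculation and the test more
stringent.  The approximation is only valid for MAF_c below 0.05 under the
assumption that very rare variants are mostly heterozygous.

PS4 is assigned when the one-sided Fisher exact test gives OR >= 20 and
p <= 0.001 and at least 2 cohort individuals carry the variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_CEILING, Decimal

from scipy.stats import fisher_exact

from .exceptions import DomainError
from .models import AnnotatedVariant, Genotype

#: preference order when auto-selecting the control frequency database
CONTROL_DB_PREFERENCE = (
    "gnomad_exome_all",
    "exac_all",
    "gnomad_genome_all",
    "gnomad_af",
    "thousand_genomes",
    "esp6500",
)


@dataclass(frozen=True)
class EnrichmentThresholds:
    """PS4 gates: OR >= 20, p <= 0.001, at least 2 cohort carriers."""

    or_threshold: float = 20.0
    p_threshold: float = 0.001
    min_carriers: int = 2


@dataclass(frozen=True)
class ControlCounts:
    """Extrapolated control pseudo-counts for one control MAF."""

    maf: float | None
    y: float
    x: int
    n_c: int
    N_c: int


@dataclass(frozen=True)
class EnrichmentResult:
    cohort_carriers: int
    cohort_noncarriers: int
    control: ControlCounts
    odds_ratio: float
    p_value: float
    ps4: bool


def maf_to_counts(maf: float | str | Decimal) -> ControlCounts:
    """Convert a control MAF in (0, 0.05) to extrapolated integer counts.

    The mantissa/exponent split uses decimal normalization of the printed
    value (not binary floating point), so e.g. 3.23e-5 splits into y = 3.23
    and x = 5 exactly.
    """
    d = Decimal(str(maf))
    if not Decimal("0") < d < Decimal("0.05"):
        raise DomainError(
            f"control MAF {maf} outside the validity domain (0, 0.05); "
            "PS4 is not evaluated for such variants"
        )
    x = -d.adjusted()
    y = d.scaleb(x)
    n_c = int(y.to_integral_value(rounding=ROUND_CEILING))
    N_c = 10**x // 2 - n_c
    return ControlCounts(maf=float(d), y=float(y), x=x, n_c=n_c, N_c=N_c)


def naive_control_counts(maf: float | str | Decimal) -> tuple[float, int, int]:
    """Standard (non-extrapolated) control carrier counts for comparison.

    Uses the same control population size T = 10^x / 2 but the unrounded
    expected carrier count m = MAF x T = y/2.  Returns ``(m, round(m), T)``;
    the unrounded m serves the odds-ratio comparison, the rounded value the
    Fisher test.  Because ceil(y) >= y/2 + 0.5 >= round(y/2) for y >= 1, the
    extrapolated test is never less stringent than this one.
    """
    d = Decimal(str(maf))
    if not Decimal("0") < d < Decimal("0.05"):
        raise DomainError(f"control MAF {maf} outside the validity domain (0, 0.05)")
    x = -d.adjusted()
    y = d.scaleb(x)
    total = 10**x // 2
    m = float(y) / 2.0
    return m, int(Decimal(m).to_integral_value()), total


def cohort_carrier_counts(v: AnnotatedVariant) -> tuple[int, int]:
    """(carriers, non-carriers) among genotyped samples; missing excluded."""
    carriers = sum(1 for g in v.genotypes.values() if g.is_carrier)
    noncarriers = sum(1 for g in v.genotypes.values() if g is Genotype.HOM_REF)
    return carriers, noncarriers


def fisher_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Rows are cohort (a carriers, b non-carriers) and control (c affected,
    d unaffected).  The p-value is the upper-tail hypergeometric sum, i.e.
    the probability of a table at least as enriched in the cohort.  The odds
    ratio is the plain cross-product ratio a*d / (b*c), reported as infinity
    when b*c = 0; degenerate margins give (0.0, 1.0) and are never assigned.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 0.0, 1.0
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else 0.0
    else:
        odds_ratio = (a * d) / (b * c)
    _, p_value = fisher_exact([[a, b], [c, d]], alternative="greater")
    return odds_ratio, float(p_value)


def assign_ps4(
    v: AnnotatedVariant,
    control_db: str | None = None,
    thresholds: EnrichmentThresholds | None = None,
    default_control_individuals: int = 50_000,
) -> EnrichmentResult | None:
    """Test one variant's cohort enrichment and decide PS4.

    ``control_db`` names the population-frequency field to use; when None the
    first available label in :data:`CONTROL_DB_PREFERENCE` is used.  A control
    frequency absent from the chosen database is treated as minimally
    observed (n_c = 1 out of ``default_control_individuals``), deliberately
    overestimating the population frequency.  Returns None (with a warning)
    when the test cannot be run: single-sample cohort, or control MAF outside
    (0, 0.05) -- such common variants meet BA1/BS1 instead.
    """
    thresholds = thresholds if thresholds is not None else EnrichmentThresholds()
    if len(v.genotypes) < 2:
        warnings.warn(
            f"PS4 skipped at {v.chrom}:{v.pos}: single-sample cohort cannot "
            f"reach the {thresholds.min_carriers}-carrier minimum",
            stacklevel=2,
        )
        return None
    if control_db is None:
        control_db = next((db for db in CONTROL_DB_PREFERENCE if db in v.pop_freqs), None)
    maf = v.pop_freqs.get(control_db) if control_db else None
    if maf is None:
        control = ControlCounts(
            maf=None, y=1.0, x=0, n_c=1, N_c=default_control_individuals - 1
        )
    else:
        try:
            control = maf_to_counts(maf)
        except DomainError:
            return None
    carriers, noncarriers = cohort_carrier_counts(v)
    odds_ratio, p_value = fisher_one_sided(carriers, noncarriers, control.n_c, control.N_c)
    ps4 = (
        odds_ratio >= thresholds.or_threshold
        and p_value <= thresholds.p_threshold
        and carriers >= thresholds.min_carriers
    )
    return EnrichmentResult(
        cohort_carriers=carriers,
        cohort_noncarriers=noncarriers,
        control=control,
        odds_ratio=odds_ratio,
        p_value=p_value,
        ps4=ps4,
    )
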
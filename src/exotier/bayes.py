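"""Categorical ACMG combining rules and the Bayesian posterior of pathogenicity.

The categorical class follows the Richards et al. (2015) combining rules.
The continuous posterior follows the Tavtigian et al. (2018) Bayesian reading
of the same framework: evidence strengths form a geometric ladder, with one
very-strong criterion worth ``odds_pvst`` (default 350) odds of pathogenicity
and each step down the ladder worth the ``exponent_scale``-th root (default
X = 2, giving exponent denominators 1 / 2 / 4 / 8 for very strong / strong /
moderate / supporting):

    OddsPath = odds_pvst ** (n_pp/X^3 + n_pm/X^2 + n_ps/X + n_pvs
                             - n_bp/X^3 - n_bs/X)
    posterior = OddsPath * prior / ((OddsPath - 1) * prior + 1)

Benign evidence enters the same exponent with negative sign, the symmetric
extension of the pathogenic ladder, so net-benign evidence pulls the posterior
below the prior.  BA1 is stand-alone: it overrides everything and forces the
posterior to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigError
from .models import (
    BENIGN_STRONG,
    BENIGN_SUPPORTING,
    PATHOGENIC_MODERATE,
    PATHOGENIC_STRONG,
    PATHOGENIC_SUPPORTING,
    PATHOGENIC_VERY_STRONG,
    CriteriaSet,
)

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
VUS = "VUS"
LIKELY_BENIGN = "likely_benign"
BENIGN = "benign"

CATEGORIES = (PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_BENIGN, BENIGN)

#: probability verdicts from the continuous posterior
VERDICT_PATHOGENIC = "pathogenic"
VERDICT_BENIGN = "benign"
VERDICT_UNKNOWN = "unknown"


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the odds-of-pathogenicity model.

    Defaults are prior = 0.10, odds_pvst = 350 and exponent_scale = 2.
    """

    prior: float = 0.10
    odds_pvst: float = 350.0
    exponent_scale: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ConfigError(f"prior must lie in (0, 1), got {self.prior}")
        if self.odds_pvst <= 1.0:
            raise ConfigError(f"odds_pvst must exceed 1, got {self.odds_pvst}")
        if self.exponent_scale < 2:
            raise ConfigError(f"exponent_scale must be >= 2, got {self.exponent_scale}")


@dataclass(frozen=True)
class Thresholds:
    """Posterior cut-offs; comparisons are inclusive on both sides.

    The recommended pairs are lenient (0.80, 0.35) and strict (0.85, 0.20).
    """

    pathogenic_cut: float = 0.80
    benign_cut: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.benign_cut < self.pathogenic_cut < 1.0:
            raise ConfigError(
                f"need 0 < benign_cut < pathogenic_cut < 1, got "
                f"({self.benign_cut}, {self.pathogenic_cut})"
            )


LENIENT_THRESHOLDS = Thresholds(0.80, 0.35)
STRICT_THRESHOLDS = Thresholds(0.85, 0.20)


@dataclass(frozen=True)
class EvidenceCounts:
    """Criteria tallies by strength class."""

    n_pvs: int = 0
    n_ps: int = 0
    n_pm: int = 0
    n_pp: int = 0
    n_bs: int = 0
    n_bp: int = 0
    ba1: bool = False

    def __post_init__(self) -> None:
        for name in ("n_pvs", "n_ps", "n_pm", "n_pp", "n_bs", "n_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_criteria(cls, criteria: CriteriaSet) -> "EvidenceCounts":
        assigned = criteria.assigned
        count = lambda group: sum(1 for c in group if c in assigned)
        return cls(
            n_pvs=count(PATHOGENIC_VERY_STRONG),
            n_ps=count(PATHOGENIC_STRONG),
            n_pm=count(PATHOGENIC_MODERATE),
            n_pp=count(PATHOGENIC_SUPPORTING),
            n_bs=count(BENIGN_STRONG),
            n_bp=count(BENIGN_SUPPORTING),
            ba1="BA1" in assigned,
        )


@dataclass(frozen=True)
class ClassificationResult:
    """Categorical class plus the continuous posterior for one variant."""

    category: str
    posterior: float
    odds_path: float
    log_odds_path: float
    verdict: str
    note: str = ""


def combine_categorical(e: EvidenceCounts) -> str:
    """Richards et al. combining rules.

    BA1 is stand-alone and wins outright.  Otherwise, evidence satisfying
    both a pathogenic-side and a benign-side rule is contradictory and the
    variant stays a VUS.
    """
    if e.ba1:
        return BENIGN
    path = (
        (e.n_pvs >= 1 and (e.n_ps >= 1 or e.n_pm >= 2 or (e.n_pm == 1 and e.n_pp == 1) or e.n_pp >= 2))
        or e.n_ps >= 2
        or (
            e.n_ps == 1
            and (e.n_pm >= 3 or (e.n_pm == 2 and e.n_pp >= 2) or (e.n_pm == 1 and e.n_pp >= 4))
        )
    )
    likely_path = (
        (e.n_pvs == 1 and e.n_pm == 1)
        or (e.n_ps == 1 and e.n_pm in (1, 2))
        or (e.n_ps == 1 and e.n_pp >= 2)
        or e.n_pm >= 3
        or (e.n_pm == 2 and e.n_pp >= 2)
        or (e.n_pm == 1 and e.n_pp >= 4)
    )
    benign = e.n_bs >= 2
    likely_benign = (e.n_bs == 1 and e.n_bp == 1) or e.n_bp >= 2
    if (path or likely_path) and (benign or likely_benign):
        return VUS
    if path:
        return PATHOGENIC
    if likely_path:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return VUS


def log_odds_path(e: EvidenceCounts, m: ModelParams | None = None) -> float:
    """Natural log of the combined odds of pathogenicity (exact in log space)."""
    m = m if m is not None else ModelParams()
    x = m.exponent_scale
    exponent = (
        (e.n_pp - e.n_bp) / x**3 + e.n_pm / x**2 + (e.n_ps - e.n_bs) / x + e.n_pvs
    )
    return exponent * math.log(m.odds_pvst)


def posterior_probability(e: EvidenceCounts, m: ModelParams | None = None) -> float:
    """Posterior probability of pathogenicity.

    With no evidence the odds are 1 and the posterior equals the prior
    exactly.  BA1 forces the posterior to 0.  The exponent is computed in log
    space; the posterior saturates to 1.0 when the odds overflow a double.
    """
    m = m if m is not None else ModelParams()
    if e.ba1:
        return 0.0
    lo = log_odds_path(e, m)
    if lo > 700.0:  # exp() would overflow; posterior is 1 to double precision
        return 1.0
    odds = math.exp(lo)
    return odds * m.prior / ((odds - 1.0) * m.prior + 1.0)


def classify(
    criteria: CriteriaSet | EvidenceCounts,
    params: ModelParams | None = None,
    thresholds: Thresholds | None = None,
) -> ClassificationResult:
    """Full classification of one variant's criteria set.

    Returns the categorical ACMG class, the posterior, and the probability
    verdict: ``pathogenic`` when posterior >= pathogenic_cut, ``benign`` when
    posterior <= benign_cut, else ``unknown`` (inclusive comparisons).
    """
    params = params if params is not None else ModelParams()
    thresholds = thresholds if thresholds is not None else LENIENT_THRESHOLDS
    e = criteria if isinstance(criteria, EvidenceCounts) else EvidenceCounts.from_criteria(criteria)
    category = combine_categorical(e)
    note = ""
    if e.ba1:
        posterior = 0.0
        odds = 0.0
        lo = -math.inf
        if e.n_pvs or e.n_ps or e.n_pm or e.n_pp:
            note = "BA1 stand-alone overrides conflicting pathogenic evidence"
    else:
        lo = log_odds_path(e, params)
        odds = math.exp(lo) if lo <= 700.0 else math.inf
        posterior = posterior_probability(e, params)
    if posterior >= thresholds.pathogenic_cut:
        verdict = VERDICT_PATHOGENIC
    elif posterior <= thresholds.benign_cut:
        verdict = VERDICT_BENIGN
    else:
        verdict = VERDICT_UNKNOWN
    return ClassificationResult(
        category=category,
        posterior=posterior,
        odds_path=odds,
        log_odds_path=lo,
        verdict=verdict,
        note=note,
    )
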
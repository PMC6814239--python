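"""Each criterion predicate, plus determinism and closed-set properties."""

import random

import pytest

from exotier.acmg import EngineConfig, assign_criteria
from exotier.fixtures import random_variant
from exotier.models import VALID_CRITERIA

from conftest import make_variant


def assigned(v, tables):
    return assign_criteria(v, tables).assigned


# one case per predicate: (variant overrides, criteria that must fire,
# criteria that must not)
PREDICATE_CASES = [
    ("pvs1_stopgain",
     dict(gene="BRCA2", exonic_func="stopgain"), {"PVS1"}, set()),
    ("pvs1_splicing",
     dict(gene="BRCA2", func_region="splicing", exonic_func=None), {"PVS1"}, set()),
    ("pvs1_needs_lof_gene",
     dict(gene="GENE1", exonic_func="stopgain"), set(), {"PVS1"}),
    ("ps1_same_aa_other_nucleotide",
     dict(gene="TP53", aa_change="p.R175H", cdna_change="c.524G>A"),
     {"PS1"}, {"PM5"}),
    ("ps1_blocked_for_identical_cdna",
     dict(gene="TP53", aa_change="p.R175H", cdna_change="c.523C>T"),
     set(), {"PS1"}),
    ("pm5_different_aa_at_hotspot",
     dict(gene="TP53", aa_change="p.R175L"), {"PM5"}, {"PS1"}),
    ("ps3_asserted_pathogenic",
     dict(clinvar_sig="Pathogenic", clinvar_status="criteria provided, single submitter"),
     {"PS3"}, {"PP5"}),
    ("pp5_unasserted_pathogenic",
     dict(clinvar_sig="Likely_pathogenic", clinvar_status="no assertion criteria provided"),
     {"PP5"}, {"PS3"}),
    ("conflicting_interpretations_fire_nothing",
     dict(clinvar_sig="Conflicting_interpretations_of_pathogenicity",
          clinvar_status="criteria provided, conflicting interpretations"),
     set(), {"PS3", "PP5", "BS3", "BP6"}),
    ("pm1_missense_in_domain",
     dict(domain_annotation="Ion transport domain"), {"PM1"}, set()),
    ("pm1_blocked_in_benign_domain",
     dict(domain_annotation="Olfactory receptor family"), set(), {"PM1"}),
    ("pm2_absent_everywhere", dict(pop_freqs={}), {"PM2"}, set()),
    ("pm2_rare_everywhere", dict(pop_freqs={"exac_all": 9e-5}), {"PM2"}, set()),
    ("pm2_blocked_by_one_common_db",
     dict(pop_freqs={"exac_all": 9e-5, "gnomad_exome_all": 2e-4}), set(), {"PM2"}),
    ("pm4_inframe_deletion",
     dict(ref="TCTG", alt="T", exonic_func="nonframeshift deletion"), {"PM4"}, set()),
    ("pm4_stoploss", dict(exonic_func="stoploss"), {"PM4"}, set()),
    ("pm4_blocked_in_repeat",
     dict(ref="TCTG", alt="T", exonic_func="nonframeshift deletion",
          repeat_region=True), set(), {"PM4"}),
    ("pp2_constrained_gene", dict(gene="SCN1A"), {"PP2"}, {"BP1"}),
    ("pp3_predictor_majority",
     dict(predictor_calls={"sift": "deleterious", "polyphen2_hdiv": "deleterious",
                           "lrt": "tolerated"}), {"PP3"}, {"BP4"}),
    ("pp3_needs_two_predictors",
     dict(predictor_calls={"sift": "deleterious"}), set(), {"PP3"}),
    ("ba1_common", dict(pop_freqs={"exac_all": 0.12}), {"BA1"}, {"PM2", "BS1"}),
    ("bs1_frequent_not_common",
     dict(pop_freqs={"exac_all": 0.02}), {"BS1"}, {"BA1", "PM2"}),
    ("bs2_homozygotes_reported", dict(hom_count=3), {"BS2"}, set()),
    ("bs2_zero_homozygotes", dict(hom_count=0), set(), {"BS2"}),
    ("bs3_asserted_benign",
     dict(clinvar_sig="Benign", clinvar_status="reviewed by expert panel"),
     {"BS3"}, {"BP6"}),
    ("bp6_unasserted_benign",
     dict(clinvar_sig="Benign/Likely_benign", clinvar_status="no assertion criteria provided"),
     {"BP6"}, {"BS3"}),
    ("bp1_truncating_mechanism_gene", dict(gene="TTN"), {"BP1"}, {"PP2"}),
    ("bp3_repeat_inframe_no_domain",
     dict(ref="A", alt="ACAG", exonic_func="nonframeshift insertion",
          repeat_region=True), {"BP3"}, {"PM4"}),
    ("bp3_blocked_by_domain",
     dict(ref="A", alt="ACAG", exonic_func="nonframeshift insertion",
          repeat_region=True, domain_annotation="Ion transport domain"),
     set(), {"BP3"}),
    ("bp4_predictor_majority",
     dict(predictor_calls={"sift": "tolerated", "polyphen2_hdiv": "tolerated",
                           "lrt": "deleterious"}), {"BP4"}, {"PP3"}),
    ("bp7_silent_no_splice_impact",
     dict(exonic_func="synonymous SNV"), {"BP7"}, set()),
    ("bp7_silent_low_splice_score",
     dict(exonic_func="synonymous SNV", splice_pred=0.2), {"BP7"}, set()),
    ("bp7_blocked_by_splice_score",
     dict(exonic_func="synonymous SNV", splice_pred=0.9), set(), {"BP7"}),
]


@pytest.mark.parametrize(
    "overrides,must,must_not",
    [c[1:] for c in PREDICATE_CASES],
    ids=[c[0] for c in PREDICATE_CASES],
)
def test_criterion_predicates(tables, overrides, must, must_not):
    got = assigned(make_variant(**overrides), tables)
    assert must <= got, f"expected {must} within {got}"
    assert not (must_not & got), f"unexpected {must_not & got}"


def test_compound_example_lof_rare(tables):
    v = make_variant(gene="BRCA2", exonic_func="stopgain", pop_freqs={})
    assert assigned(v, tables) == {"PVS1", "PM2"}


def test_compound_example_silent_benign_predictors(tables):
    v = make_variant(
        exonic_func="synonymous SNV",
        splice_pred=0.1,
        predictor_calls={"sift": "tolerated", "polyphen2_hdiv": "tolerated"},
    )
    assert assigned(v, tables) == {"BP7", "BP4"}


def test_missing_annotations_fire_nothing(tables):
    v = make_variant(gene=None, func_region=None, exonic_func=None, pop_freqs={})
    assert assigned(v, tables) == {"PM2"}  # absence from all databases is evidence


def test_assignment_is_deterministic(tables):
    rng = random.Random(7)
    for i in range(50):
        v = random_variant(rng, i)
        first = assign_criteria(v, tables)
        second = assign_criteria(v, tables)
        assert first.assigned == second.assigned
        assert first.evidence_notes == second.evidence_notes


def test_closed_set_and_exclusions_on_fuzzed_variants(tables):
    rng = random.Random(11)
    for i in range(300):
        got = assigned(random_variant(rng, i), tables)
        assert got <= VALID_CRITERIA
        assert not {"BA1", "PM2"} <= got
        assert not {"BA1", "PS4"} <= got
        assert not {"PS1", "PM5"} <= got


def test_notes_populated_for_every_assigned_criterion(tables):
    rng = random.Random(3)
    for i in range(100):
        cs = assign_criteria(random_variant(rng, i), tables)
        assert set(cs.evidence_notes) == cs.assigned


UNRELATED = {
    "predictor_calls": {"PP3", "BP4"},
    "clinvar": {"PS3", "PP5", "BS3", "BP6"},
    "domain_annotation": {"PM1", "BP3"},
    "hom_count": {"BS2"},
}


def test_monotone_annotation_growth(tables):
    """Adding one annotation field may add criteria but never removes one
    assigned from unrelated evidence."""
    import dataclasses

    rng = random.Random(23)
    for i in range(120):
        v = random_variant(rng, i)
        base = dataclasses.replace(
            v, predictor_calls={}, clinvar_sig=None, clinvar_status=None,
            domain_annotation=None, hom_count=None,
        )
        before = assigned(base, tables)
        for field_name, related in UNRELATED.items():
            if field_name == "predictor_calls":
                grown = dataclasses.replace(base, predictor_calls=v.predictor_calls)
            elif field_name == "clinvar":
                grown = dataclasses.replace(
                    base, clinvar_sig=v.clinvar_sig, clinvar_status=v.clinvar_status
                )
            elif field_name == "domain_annotation":
                grown = dataclasses.replace(base, domain_annotation=v.domain_annotation)
            else:
                grown = dataclasses.replace(base, hom_count=v.hom_count)
            after = assigned(grown, tables)
            assert before - related <= after, (
                f"adding {field_name} removed {before - related - after}"
            )


def test_config_thresholds_are_effective(tables, tmp_path):
    v = make_variant(pop_freqs={"exac_all": 5e-4})
    assert "PM2" not in assigned(v, tables)
    lax = EngineConfig(rare_threshold=1e-3)
    assert "PM2" in assign_criteria(v, tables, lax).assigned
    cfg_file = tmp_path / "thresholds.cfg"
    cfg_file.write_text("rare_threshold = 1e-3\n")
    assert EngineConfig.from_file(cfg_file) == lax
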
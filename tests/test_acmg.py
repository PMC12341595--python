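"""ACMG/AMP criterion derivation and evidence combination."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abca1func.acmg import (
    MODERATE,
    STRONG,
    SUPPORTING,
    CriterionEvidence,
    classify_variant,
    combine,
    frequency_criteria,
    functional_criterion,
    phenotype_criterion,
    reclassification_report,
    validate_assay,
)
from abca1func.domains import VariantRecord
from abca1func.efflux import LOSS_OF_FUNCTION, NORMAL, UNCERTAIN
from abca1func.errors import UnknownCriterionError
from helpers_acmg import all_multisets, brute_combine


def ev(*tokens):
    return tuple(CriterionEvidence.from_token(t) for t in tokens)


class TestCriterionEvidence:
    @pytest.mark.parametrize(
        ("token", "code", "strength"),
        [
            ("PM2", "PM2", MODERATE),
            ("PM1_supporting", "PM1", SUPPORTING),
            ("PP4_strong", "PP4", STRONG),
            ("BS3_moderate", "BS3", MODERATE),
            ("BA1", "BA1", "stand_alone"),
            ("PVS1", "PVS1", "very_strong"),
        ],
    )
    def test_token_parsing_and_native_strengths(self, token, code, strength):
        c = CriterionEvidence.from_token(token)
        assert (c.code, c.strength) == (code, strength)
        assert c.token == token

    @pytest.mark.parametrize("bad", ["PX9", "PM9", "PM2_weak", "BS1_very_strong", ""])
    def test_invalid_tokens_rejected(self, bad):
        with pytest.raises(UnknownCriterionError):
            CriterionEvidence.from_token(bad)


class TestDerivedCriteria:
    @pytest.mark.parametrize(
        ("faf", "expected"),
        [
            (0.006, "BA1"),
            (0.005, "BA1"),    # inclusive cutoff
            (0.003, "BS1"),
            (0.002, "BS1"),
            (0.0001, "PM2"),
            (0.0002, "PM2"),   # inclusive cutoff
            (0.001, None),     # between PM2 and BS1
            (None, None),
        ],
    )
    def test_frequency_tiers(self, faf, expected, config):
        got = frequency_criteria(faf, config)
        assert (got.code if got else None) == expected

    @pytest.mark.parametrize(
        ("hdl", "tangier", "expected"),
        [
            (0.45, False, ("PP4", SUPPORTING)),
            (0.25, False, ("PP4", MODERATE)),
            (0.05, False, ("PP4", STRONG)),
            (None, True, ("PP4", STRONG)),     # Tangier alone is strong
            (0.45, True, ("PP4", STRONG)),     # strictest tier wins
            (0.8, False, None),
            (None, False, None),
        ],
    )
    def test_phenotype_tiers(self, hdl, tangier, expected, config):
        got = phenotype_criterion(hdl, tangier, config)
        assert ((got.code, got.strength) if got else None) == expected

    def test_negative_hdl_rejected(self, config):
        with pytest.raises(ValueError):
            phenotype_criterion(-0.1, False, config)

    @pytest.mark.parametrize(
        ("category", "expected"),
        [
            (LOSS_OF_FUNCTION, ("PS3", MODERATE)),
            (NORMAL, ("BS3", MODERATE)),
            (UNCERTAIN, None),
        ],
    )
    def test_functional_criterion(self, category, expected):
        got = functional_criterion(category, MODERATE)
        assert ((got.code, got.strength) if got else None) == expected

    @pytest.mark.parametrize(
        ("n_controls", "nn", "reps", "expected"),
        [
            (15, True, True, MODERATE),
            (11, True, True, MODERATE),   # inclusive boundary
            (10, True, True, SUPPORTING),
            (5, True, True, SUPPORTING),
            (15, False, True, SUPPORTING),
            (15, True, False, SUPPORTING),
        ],
    )
    def test_assay_validation_rule(self, n_controls, nn, reps, expected, config):
        assert validate_assay(n_controls, nn, reps, config) == expected


class TestCombine:
    @pytest.mark.parametrize(
        ("tokens", "expected"),
        [
            (("PM2", "PM3", "PP3", "PP4_strong", "PS3_moderate"), 5),
            (("PM2", "PM3", "PP3", "PP4_strong"), 4),
            (("BS1", "BS3_moderate"), 2),
            (("BS1",), 3),
            ((), 3),
            (("PM2", "PP3", "PP4", "PS3_moderate"), 4),
            (("PM2", "PP3", "PP4"), 3),
            (("BA1",), 1),
            (("BS1", "BS2"), 1),
            (("BP4", "BS3_moderate"), 2),   # moderate benign = two supporting
            (("PVS1", "PM2"), 4),
            (("PVS1", "PS1"), 5),
            (("PM2", "PS3_moderate", "BS3_moderate"), 3),  # conflict
        ],
    )
    def test_combining_rules(self, tokens, expected):
        assert combine(ev(*tokens)) == expected

    def test_order_invariance(self):
        tokens = ("PM2", "PM3", "PP3", "PP4_strong", "PS3_moderate")
        for perm in itertools.permutations(tokens):
            assert combine(ev(*perm)) == 5

    def test_duplicate_codes_rejected(self):
        with pytest.raises(UnknownCriterionError, match="duplicate"):
            combine(ev("PM2") + ev("PM2"))

    def test_agrees_with_bruteforce_on_all_multisets_up_to_size_4(self):
        n = 0
        for criteria in all_multisets(max_size=4):
            assert combine(criteria) == brute_combine(criteria), [
                c.token for c in criteria
            ]
            n += 1
        assert n > 60  # the enumeration is not vacuous

    def test_adding_ps3_moderate_never_yields_benign_class(self):
        for criteria in all_multisets(max_size=3):
            if any(c.code == "PS3" for c in criteria):
                continue
            if combine(criteria) == 3:
                with_ps3 = criteria + ev("PS3_moderate")
                assert combine(with_ps3) >= 3

    @given(st.permutations(["PM2", "PM3", "PP3", "BS1", "BP4"]))
    @settings(max_examples=60, derandomize=True)
    def test_any_subset_order_invariant(self, tokens):
        for k in range(len(tokens) + 1):
            subset = tokens[:k]
            assert combine(ev(*subset)) == combine(ev(*sorted(subset)))


class TestClassifyVariant:
    def test_asserted_plus_functional(self, config):
        v = VariantRecord.from_name("p.S1157N", asserted_criteria=ev("BP4"))
        r = classify_variant(v, NORMAL, config)
        assert (r.class_without_functional, r.class_with_functional) == (3, 2)
        assert r.changed

    def test_no_asserted_criteria_with_normal_assay(self, config):
        v = VariantRecord.from_name("p.N1185S")
        r = classify_variant(v, NORMAL, config)
        assert (r.class_without_functional, r.class_with_functional) == (3, 2)

    def test_uncertain_category_changes_nothing(self, config):
        v = VariantRecord.from_name("p.R2080Q", asserted_criteria=ev("PM2"))
        r = classify_variant(v, UNCERTAIN, config)
        assert not r.changed

    def test_frequency_and_phenotype_rules_fire(self, config):
        v = VariantRecord.from_name(
            "p.F2009S", filtering_allele_frequency=1e-5, hdl_c=0.05,
        )
        r = classify_variant(v, LOSS_OF_FUNCTION, config)
        codes = {c.code for c in r.criteria_without}
        assert codes == {"PM2", "PP4"}
        strengths = {c.code: c.strength for c in r.criteria_without}
        assert strengths["PP4"] == STRONG

    def test_derived_criterion_skipped_when_asserted(self, config):
        v = VariantRecord.from_name(
            "p.F2009S", filtering_allele_frequency=1e-5,
            asserted_criteria=ev("PM2"),
        )
        r = classify_variant(v, None, config)
        assert [c.code for c in r.criteria_without].count("PM2") == 1

    def test_supporting_strength_assay(self, config):
        v = VariantRecord.from_name("p.N1185S")
        r = classify_variant(v, NORMAL, config, assay_valid_strength=SUPPORTING)
        # one supporting benign criterion alone cannot reach likely benign
        assert r.class_with_functional == 3


class TestReclassificationReport:
    def test_empty_input(self):
        report = reclassification_report([])
        assert report.n_variants == 0 and report.n_changed == 0
        assert report.transitions == {}

    def test_transition_counting(self, config):
        variants = [
            (VariantRecord.from_name("p.S1157N", asserted_criteria=ev("BP4")),
             NORMAL),
            (VariantRecord.from_name("p.L1033P",
                                     asserted_criteria=ev("PM2", "PP3", "PP4")),
             LOSS_OF_FUNCTION),
            (VariantRecord.from_name("p.R2080Q", asserted_criteria=ev("PM2")),
             UNCERTAIN),
        ]
        results = [classify_variant(v, cat, config) for v, cat in variants]
        report = reclassification_report(results)
        assert report.n_variants == 3 and report.n_changed == 2
        assert report.transitions == {"3->2": 1, "3->4": 1}
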
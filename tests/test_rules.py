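"""Rules engine: DSL parsing, first-match variant assignment, BPM assembly."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vitaprof.rules import (
    VITAMINS,
    FALLBACK_CODE,
    GenePresenceProfile,
    RuleParseError,
    assign_variant,
    build_bpm,
    match_rule,
    parse_ruleset,
    render_ruleset,
)

MINI_DOC = """
[vocabulary]
RibA RibB RibD RibH RibE RibF

[B2]
P 1 : (RibA), RibB, RibD, RibH, RibE, RibF
A 0 : RibF
"""


def profile(*roles):
    return GenePresenceProfile("g", frozenset(roles))


class TestParsing:
    def test_riboflavin_line_structure(self, ruleset):
        rule = ruleset.rule("B2", "P")
        assert len(rule.terms) == 6
        assert sum(not t.required for t in rule.terms) == 1
        assert rule.terms[0].alternatives == ("RibA",)
        assert rule.binary_phenotype == 1

    def test_any_of_alternatives(self, ruleset):
        rule = ruleset.rule("B1", "A")
        assert len(rule.terms) == 1
        assert rule.terms[0].alternatives == ("ThiL", "ThiN")
        assert rule.binary_phenotype == 0

    def test_empty_signature_matches_anything(self, ruleset):
        rule = ruleset.rule("Q", "A")
        assert rule.terms == ()
        assert match_rule(profile(), rule)
        assert match_rule(profile("qTGT", "QueA"), rule)

    def test_requirements_note_carried(self, ruleset):
        assert ruleset.rule("B1", "Az").requirements_note == "B1; HET"

    def test_unknown_role_names_line(self):
        doc = MINI_DOC.replace("A 0 : RibF", "A 0 : RibF, Bogus")
        with pytest.raises(RuleParseError, match=r"line \d+.*Bogus"):
            parse_ruleset(doc)

    def test_empty_any_of_group(self):
        doc = MINI_DOC.replace("RibB,", "RibB//RibD,")
        with pytest.raises(RuleParseError, match="empty any-of"):
            parse_ruleset(doc)

    def test_duplicate_variant_code(self):
        doc = MINI_DOC + "A 0 : RibE\n"
        with pytest.raises(RuleParseError, match="duplicate variant code"):
            parse_ruleset(doc)

    def test_code_letter_phenotype_consistency(self):
        doc = MINI_DOC.replace("A 0 : RibF", "A 1 : RibF")
        with pytest.raises(RuleParseError, match="inconsistent"):
            parse_ruleset(doc)

    def test_render_parse_round_trip(self, ruleset):
        again = parse_ruleset(render_ruleset(ruleset))
        assert again.vocabulary == ruleset.vocabulary
        for vitamin in ruleset.rules:
            assert [r.render() for r in again.rules[vitamin]] == [
                r.render() for r in ruleset.rules[vitamin]
            ]


class TestMatching:
    @pytest.mark.parametrize(
        "roles, vitamin, code, expected",
        [
            ({"ThiL"}, "B1", "A", True),
            ({"ThiN", "ThiM"}, "B1", "Az", False),
            (set(), "Q", "A", True),
        ],
    )
    def test_match_rule(self, ruleset, roles, vitamin, code, expected):
        rule = ruleset.rule(vitamin, code)
        assert match_rule(GenePresenceProfile("g", frozenset(roles)), rule) is expected

    def test_optional_terms_do_not_affect_match(self, ruleset):
        rule = ruleset.rule("B2", "P")
        base = {"RibB", "RibD", "RibH", "RibE", "RibF"}
        assert match_rule(profile(*base), rule)
        assert match_rule(profile(*base, "RibA"), rule)


class TestAssignment:
    @pytest.mark.parametrize(
        "roles, vitamin, code, bp",
        [
            ({"RibB", "RibD", "RibH", "RibE", "RibF"}, "B2", "P", 1),
            ({"RibF"}, "B2", "A", 0),
            ({"ThiC", "ThiD", "ThiE", "ThiM", "ThiN"}, "B1", "Az", 0),
        ],
    )
    def test_first_match_assignment(self, ruleset, roles, vitamin, code, bp):
        a = assign_variant(GenePresenceProfile("g", frozenset(roles)), ruleset, vitamin)
        assert (a.variant_code, a.binary_phenotype) == (code, bp)

    def test_fallback_for_unmatched_profile(self, ruleset):
        a = assign_variant(profile(), ruleset, "B1")
        assert a.variant_code == FALLBACK_CODE
        assert a.binary_phenotype == 0
        assert a.is_fallback

    def test_minimal_profile_recovers_every_rule(self, ruleset):
        """Round-trip: each rule's minimal satisfying profile is assigned
        exactly that rule (the bundled set is most-complete-first)."""
        for vitamin, rules in ruleset.rules.items():
            for rule in rules:
                p = GenePresenceProfile("g", rule.minimal_profile())
                a = assign_variant(p, ruleset, vitamin)
                assert a.variant_code == rule.variant_code, (vitamin, rule.variant_code)


class TestBPM:
    def test_prototroph_row_all_ones(self, ruleset):
        roles = frozenset().union(
            *(ruleset.rules[v][0].minimal_profile() for v in VITAMINS)
        )
        bpm = build_bpm([GenePresenceProfile("g", roles)], ruleset)
        assert bpm.phenotypes.loc["g"].tolist() == [1] * 9

    def test_empty_profile_row_all_zeros(self, ruleset):
        bpm = build_bpm([profile()], ruleset)
        assert bpm.phenotypes.loc["g"].tolist() == [0] * 9
        # every code is either the fallback or an empty-signature A rule
        for vitamin, code in bpm.variants.loc["g"].items():
            assert code == FALLBACK_CODE or not ruleset.rule(vitamin, code).terms

    def test_duplicate_genome_ids_rejected(self, ruleset):
        with pytest.raises(ValueError, match="duplicate genome ids"):
            build_bpm([profile(), profile()], ruleset)

    def test_planted_variants_recovered(self, small_reference):
        bpm = small_reference.bpm()
        assert bpm.variants.equals(small_reference.true_variants)
        assert bpm.phenotypes.equals(small_reference.true_phenotypes)


@st.composite
def role_subsets(draw, ruleset):
    vocab = sorted(ruleset.vocabulary)
    return frozenset(draw(st.sets(st.sampled_from(vocab), max_size=25)))


@pytest.fixture(scope="module")
def vocab_strategy(ruleset):
    return role_subsets(ruleset)


class TestProperties:
    @given(data=st.data())
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotonicity_and_code_sign(self, ruleset, data):
        """Adding roles can only move an assignment to an earlier (more
        complete) rule, and P/A code letters always match the phenotype."""
        roles = data.draw(role_subsets(ruleset))
        extra = data.draw(role_subsets(ruleset))
        vitamin = data.draw(st.sampled_from(VITAMINS))
        order = {r.variant_code: r.order_index for r in ruleset.rules[vitamin]}
        order[FALLBACK_CODE] = len(order)

        a1 = assign_variant(GenePresenceProfile("g", roles), ruleset, vitamin)
        a2 = assign_variant(GenePresenceProfile("g", roles | extra), ruleset, vitamin)
        assert order[a2.variant_code] <= order[a1.variant_code]
        for a in (a1, a2):
            if a.variant_code.startswith("P"):
                assert a.binary_phenotype == 1
            else:
                assert a.binary_phenotype == 0

    @given(data=st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_determinism(self, ruleset, data):
        roles = data.draw(role_subsets(ruleset))
        p = GenePresenceProfile("g", roles)
        for vitamin in VITAMINS:
            assert assign_variant(p, ruleset, vitamin) == assign_variant(
                p, ruleset, vitamin
            )
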
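"""Feature system: encoding features per DP type, retrieval feature counts,
and distinctive-cue counting under the two person-cue hypotheses."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from frec.features import (
    AssignmentTable,
    ConfigError,
    CueConfig,
    DPTemplate,
    DPType,
    Probe,
    distinctive_cue_count,
    dp_encoding_features,
    load_assignment_table,
    load_cue_config,
    retrieval_feature_count,
    save_config,
)

DEF = DPTemplate(DPType.DEFINITE, person=3, number="sg")
PROP = DPTemplate(DPType.PROPER, person=3, number="sg")
WE = DPTemplate(DPType.BARE_PRONOUN, person=1, number="pl", case_overt=True, case="nom")
YOU = DPTemplate(DPType.BARE_PRONOUN, person=2, number="pl")
PRO2 = DPTemplate(DPType.RESTRICTED_PRONOUN, person=2, number="pl", out_of_the_blue=True)
ART_PL = DPTemplate(DPType.DEFINITE, person=3, number="pl")

PLAIN = Probe()
AGR = Probe(agreement=frozenset({"person", "number"}))
NOM_CASE = Probe(case="nom")


class TestDpEncodingFeatures:
    @pytest.mark.parametrize(
        "template, total",
        [
            (DEF, 2),  # a determiner and a nominal restriction
            (PROP, 1),  # salient index free, name restriction costs 1
            (YOU, 0),  # deictic pronoun: contextually pre-activated
            (PRO2, 3),  # D + N + out-of-the-blue speech-act participant
        ],
    )
    def test_per_type_totals(self, template, total, table):
        features = dp_encoding_features(template, table)
        assert sum(w for _, w in features) == total

    def test_licensed_restricted_pronoun_skips_accommodation(self, table):
        licensed = DPTemplate(DPType.RESTRICTED_PRONOUN, person=2, out_of_the_blue=False)
        assert sum(w for _, w in dp_encoding_features(licensed, table)) == 2

    def test_definite_encodes_d_and_n(self, table):
        names = [f.value for f, _ in dp_encoding_features(DEF, table)]
        assert names == ["D", "N"]


class TestRetrievalFeatureCount:
    def test_definite_always_two(self, table, italian_cue):
        for competitors in ([], [PROP], [PRO2]):
            assert retrieval_feature_count(DEF, competitors, PLAIN, italian_cue, table) == 2

    def test_proper_confused_by_same_person_proper(self, table, english_cue):
        # the salient-index shortcut is lost against a same-person salient competitor
        assert retrieval_feature_count(PROP, [PROP], PLAIN, english_cue, table) == 2
        assert retrieval_feature_count(PROP, [], PLAIN, english_cue, table) == 1
        assert retrieval_feature_count(PROP, [DEF], PLAIN, english_cue, table) == 1

    def test_pronoun_keeps_shortcut_against_definite(self, table, english_cue):
        assert retrieval_feature_count(WE, [DEF], PLAIN, english_cue, table) == 1

    def test_pronoun_keeps_shortcut_against_other_person(self, table, english_cue):
        assert retrieval_feature_count(WE, [YOU], PLAIN, english_cue, table) == 1

    def test_marked_person_bonus_only_under_agreement(self, table, italian_cue):
        # the agreeing subject probe adds the marked-person feature ...
        assert retrieval_feature_count(PRO2, [ART_PL], AGR, italian_cue, table) == 3
        # ... the non-agreeing object probe does not
        assert retrieval_feature_count(PRO2, [], PLAIN, italian_cue, table) == 2

    def test_third_person_never_earns_bonus(self, table, italian_cue):
        assert retrieval_feature_count(ART_PL, [PRO2], AGR, italian_cue, table) == 2

    def test_restricted_pronoun_has_no_shortcut_to_lose(self, table, italian_cue):
        same = retrieval_feature_count(PRO2, [PRO2], AGR, italian_cue, table)
        alone = retrieval_feature_count(PRO2, [ART_PL], AGR, italian_cue, table)
        assert same == alone == 3


class TestDistinctiveCueCount:
    def test_empty_competitor_set(self, italian_cue):
        assert distinctive_cue_count(PRO2, [], AGR, italian_cue) == 0

    def test_marked_person_mismatch_is_distinctive_under_h2(self, italian_cue):
        assert distinctive_cue_count(PRO2, [ART_PL], AGR, italian_cue) == 1

    def test_matched_marked_persons_are_not_distinctive(self, italian_cue):
        assert distinctive_cue_count(PRO2, [PRO2], AGR, italian_cue) == 0

    def test_unmarked_person_not_distinctive_under_h2(self, italian_cue):
        assert distinctive_cue_count(ART_PL, [PRO2], AGR, italian_cue) == 0

    def test_any_person_mismatch_distinctive_under_h1(self):
        h1 = CueConfig.italian("H1")
        assert distinctive_cue_count(ART_PL, [PRO2], AGR, h1) == 1

    def test_uncued_dimension_ignored(self, english_cue):
        # the English past-tense probe carries no phi agreement
        assert distinctive_cue_count(PRO2, [ART_PL], PLAIN, english_cue) == 0

    def test_overt_case_is_a_cue(self, english_cue):
        assert distinctive_cue_count(WE, [DEF], NOM_CASE, english_cue) == 1

    def test_caseless_pronoun_earns_no_case_cue(self, english_cue):
        assert distinctive_cue_count(YOU, [DEF], NOM_CASE, english_cue) == 0

    def test_number_mismatch_distinctive_when_cued(self, italian_cue):
        sg = DPTemplate(DPType.DEFINITE, person=3, number="sg")
        assert distinctive_cue_count(sg, [ART_PL], AGR, italian_cue) == 1


persons = st.sampled_from([1, 2, 3])
numbers = st.sampled_from(["sg", "pl"])
types = st.sampled_from(list(DPType))


@st.composite
def templates(draw):
    t = draw(types)
    person = draw(persons)
    if t is DPType.RESTRICTED_PRONOUN:
        person = draw(st.sampled_from([1, 2]))
    case_overt = draw(st.booleans())
    return DPTemplate(
        t, person=person, number=draw(numbers),
        case_overt=case_overt, case="nom" if case_overt else None,
        out_of_the_blue=draw(st.booleans()),
    )


class TestCueProperties:
    @given(competitors=st.lists(templates(), max_size=4))
    def test_h2_is_blind_to_third_person_targets(self, competitors):
        """Under H2 swapping one person-3 target for another identical
        person-3 target never changes dF."""
        cue = CueConfig.italian("H2")
        a = DPTemplate(DPType.DEFINITE, person=3, number="pl")
        b = DPTemplate(DPType.PROPER, person=3, number="pl")
        da = distinctive_cue_count(a, competitors, AGR, cue)
        db = distinctive_cue_count(b, competitors, AGR, cue)
        assert da == db

    @given(target=templates(), competitors=st.lists(templates(), min_size=1, max_size=4))
    def test_identical_competitor_cannot_raise_df(self, target, competitors):
        """Adding a competitor identical to the target on all cued
        dimensions can only decrease or preserve dF."""
        for cue in (CueConfig.italian("H1"), CueConfig.italian("H2"), CueConfig.english()):
            probe = Probe(agreement=frozenset({"person", "number"}), case="nom")
            before = distinctive_cue_count(target, competitors, probe, cue)
            after = distinctive_cue_count(target, competitors + [target], probe, cue)
            assert after <= before


class TestConfigValidation:
    def test_restricted_pronoun_rejects_default_person(self):
        with pytest.raises(ConfigError):
            DPTemplate(DPType.RESTRICTED_PRONOUN, person=3)

    def test_case_overt_requires_case_value(self):
        with pytest.raises(ConfigError):
            DPTemplate(DPType.BARE_PRONOUN, person=1, case_overt=True)

    def test_bad_hypothesis(self):
        with pytest.raises(ConfigError):
            CueConfig(hypothesis="H3")

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigError):
            AssignmentTable(person_nf_bonus=-1)

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_config_file_round_trip(self, tmp_path, suffix):
        cue = CueConfig.italian("H1")
        table = AssignmentTable(person_nf_bonus=2)
        cue_path = tmp_path / f"cue{suffix}"
        table_path = tmp_path / f"table{suffix}"
        save_config(cue, cue_path)
        save_config(table, table_path)
        assert load_cue_config(cue_path) == cue
        assert load_assignment_table(table_path) == table
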
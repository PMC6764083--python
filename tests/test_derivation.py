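"""Derivation engine: store/retrieve bookkeeping, trace invariants, the
(m, nF, dF) tuples behind every printed retrieval cost, and diagnostics."""

import json

import pytest

from frec import (
    AssignmentTable,
    CueConfig,
    DPTemplate,
    DPType,
    IncompleteDerivationError,
    LexicalItem,
    Region,
    RegionId,
    RetrieveEvent,
    SelectFeature,
    StoreEvent,
    UnretrievedFillerError,
    derive,
    english_paradigm,
    italian_paradigm,
    make_declarative_condition,
    make_subject_cleft_condition,
    trace_to_retrievals,
)


def cue_for(language):
    return CueConfig.english() if language == "english" else CueConfig.italian("H2")


def all_conditions():
    out = []
    for paradigm in (english_paradigm(), italian_paradigm()):
        for condition in paradigm.conditions:
            out.append((paradigm.language, condition))
    return out


def oracle_verb_tuples(condition, language):
    """Brute-force expectation for the verb-region (m, nF, dF) tuples.

    Independent of the engine and of the feature-system helpers: the cleft
    schema stores exactly [DP1, DP2]; the agreeing/nominative slot
    retrieves the subject first (m=2, competitor DP1), then the object
    slot retrieves DP1 (m=1, no competitors).  nF/dF arithmetic is spelled
    out literally.
    """
    base = {
        DPType.DEFINITE: 2,
        DPType.PROPER: 1,
        DPType.BARE_PRONOUN: 1,
        DPType.RESTRICTED_PRONOUN: 2,
    }
    dp1, dp2 = condition.dp1, condition.dp2
    agreeing = language == "italian"

    # subject retrieval: competitor is the focalized object
    nf2 = base[dp2.dp_type]
    if agreeing and dp2.person in (1, 2):
        nf2 += 1  # marked person probed by overt agreement
    if (
        dp2.dp_type in (DPType.PROPER, DPType.BARE_PRONOUN)
        and dp1.dp_type is not DPType.DEFINITE
        and dp1.person == dp2.person
    ):
        nf2 += 1  # salient-index shortcut lost to a same-person competitor
    df2 = 0
    if agreeing and dp2.person in (1, 2) and dp2.person != dp1.person:
        df2 += 1  # H2 marked-person cue
    if agreeing and dp2.number != dp1.number:
        df2 += 1
    if language == "english" and dp2.case_overt and not dp1.case_overt:
        df2 += 1  # nominative morphology as a cue

    # object retrieval: buffer holds only the target
    nf1 = base[dp1.dp_type]
    return [(2, nf2, df2), (1, nf1, 0)]


class TestCleftTraces:
    @pytest.mark.parametrize(
        "language, condition", all_conditions(), ids=lambda v: getattr(v, "label", v)
    )
    def test_verb_tuples_match_bruteforce_oracle(self, language, condition, table):
        trace = derive(condition.regions, cue_for(language), table, label=condition.label)
        got = [(e.m, e.n_f, e.d_f) for e in trace.retrievals(RegionId.VERB)]
        assert got == oracle_verb_tuples(condition, language)

    @pytest.mark.parametrize(
        "language, condition", all_conditions(), ids=lambda v: getattr(v, "label", v)
    )
    def test_buffer_conservation_and_m_sequence(self, language, condition, table):
        trace = derive(condition.regions, cue_for(language), table)
        stores = trace.stores()
        retrievals = trace.retrievals()
        assert len(stores) == len(retrievals) == 2
        ms = [e.m for e in retrievals]
        assert ms == sorted(ms, reverse=True) and len(set(ms)) == len(ms)

    def test_subject_stored_then_retrieved_before_object(self, english, table, english_cue):
        condition = english.condition("D1-D2")
        trace = derive(condition.regions, english_cue, table)
        stored = [e.region for e in trace.events if isinstance(e, StoreEvent)]
        assert stored == [RegionId.DP1, RegionId.DP2]
        retrieved = [e.target.label for e in trace.retrievals(RegionId.VERB)]
        assert retrieved == ["the lawyer", "the banker"]  # subject first

    def test_derive_is_deterministic(self, italian, table, italian_cue):
        condition = italian.condition("Pro1-Pro2")
        first = derive(condition.regions, italian_cue, table, label=condition.label)
        second = derive(condition.regions, italian_cue, table, label=condition.label)
        assert first == second


class TestOtherSchemata:
    def test_subject_cleft_stores_and_retrieves_once(self, table, english_cue):
        condition = make_subject_cleft_condition(
            "SC", "english",
            {"BE": "It was", "DP1": "the banker", "C": "that",
             "VERB": "avoided", "OBJ": "the lawyer", "SPILL": "at the party"},
            DPTemplate(DPType.DEFINITE, number="sg", label="the banker"),
            DPTemplate(DPType.DEFINITE, number="sg", label="the lawyer"),
        )
        trace = derive(condition.regions, english_cue, table)
        assert len(trace.stores()) == 1
        retrievals = trace.retrievals()
        assert len(retrievals) == 1 and retrievals[0].m == 1

    def test_declarative_needs_no_memory(self, table, english_cue):
        condition = make_declarative_condition(
            "SVO", "english",
            "the lawyer", DPTemplate(DPType.DEFINITE, number="sg", label="the lawyer"),
            "avoided",
            "the banker", DPTemplate(DPType.DEFINITE, number="sg", label="the banker"),
        )
        trace = derive(condition.regions, english_cue, table)
        assert trace.stores() == ()
        assert trace.retrievals() == ()


class TestRetrievalAccess:
    def test_verb_retrievals_of_hardest_condition(self, english, table, english_cue):
        trace = derive(english.condition("D1-D2").regions, english_cue, table)
        got = [(e.m, e.n_f, e.d_f) for e in trace_to_retrievals(trace, RegionId.VERB)]
        assert got == [(2, 2, 0), (1, 2, 0)]

    def test_no_retrieval_before_the_verb(self, english, table, english_cue):
        trace = derive(english.condition("D1-D2").regions, english_cue, table)
        assert trace_to_retrievals(trace, RegionId.DP1) == ()

    def test_matching_pronoun_condition_tuples(self, italian, table, italian_cue):
        trace = derive(italian.condition("Pro1-Pro2").regions, italian_cue, table)
        got = [(e.m, e.n_f, e.d_f) for e in trace_to_retrievals(trace, "VERB")]
        assert got == [(2, 3, 0), (1, 2, 0)]

    def test_unknown_region_rejected(self, english, table, english_cue):
        trace = derive(english.condition("D1-D2").regions, english_cue, table)
        with pytest.raises(Exception, match="unknown region"):
            trace_to_retrievals(trace, "VP")


class TestDiagnostics:
    def test_truncated_input_reports_open_expectation(self, english, table, english_cue):
        regions = english.condition("D1-D2").regions[:4]  # stop before the verb
        with pytest.raises(IncompleteDerivationError) as err:
            derive(regions, english_cue, table)
        assert err.value.region is RegionId.DP2

    def test_nonselecting_verb_reports_unretrieved_fillers(self, english, table, english_cue):
        condition = english.condition("D1-D2")
        lazy_verb = Region(
            RegionId.VERB, "avoided",
            (LexicalItem("avoided", ("T", "V")),),  # no select features
        )
        regions = condition.regions[:4] + (lazy_verb,)
        with pytest.raises(UnretrievedFillerError) as err:
            derive(regions, english_cue, table)
        assert err.value.region is RegionId.DP1

    def test_unexpected_category_names_region(self, table, english_cue):
        regions = (
            Region(RegionId.BE, "It was",
                   (LexicalItem("It was", ("Cop",), (SelectFeature("C"),)),)),
            Region(RegionId.VERB, "avoided", (LexicalItem("avoided", ("T", "V")),)),
        )
        with pytest.raises(Exception, match="unexpected category"):
            derive(regions, english_cue, table)


class TestTraceExport:
    def test_jsonl_lines_parse_and_cover_all_events(self, english, table, english_cue):
        condition = english.condition("N1-P2")
        trace = derive(condition.regions, english_cue, table, label=condition.label)
        lines = trace.to_jsonl().strip().splitlines()
        records = [json.loads(line) for line in lines]
        assert len(records) == len(trace.events)
        kinds = {r["event"] for r in records}
        assert kinds == {"merge", "store", "retrieve", "encode"}
        retrieve = [r for r in records if r["event"] == "retrieve"]
        assert retrieve[0]["m"] == 2 and retrieve[1]["m"] == 1

    def test_text_listing_mentions_memory_operations(self, italian, table, italian_cue):
        condition = italian.condition("Art1-Pro2")
        trace = derive(condition.regions, italian_cue, table, label=condition.label)
        listing = trace.to_text()
        assert "store" in listing and "retrieve" in listing
        assert "voi avvocati" in listing
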
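"""Top-down, left-to-right merge derivations with a memory buffer.

The engine builds structure with a single operation, merge, attaching each
incoming lexical item to the right edge of the tree built so far.  Select
features (=X) on a merged item project *expectations*: the categories that
must come next.  When an item arrives whose outer category is currently
expected, it is merged in place; when an argument (outer category D)
arrives unselected — the focalized object of a cleft, or the preverbal
subject — it is merged and a copy is *stored* in the memory buffer.  When
a later select feature asks for a category that a buffered item can
satisfy, the item is *retrieved* (re-merged) instead of expecting new
input: this is how the filler-gap dependency is closed at the verb.

Each retrieval is recorded with the triple (m, nF, dF) — buffer size at
retrieval (target included), features to recover, distinctive cued
features — which :mod:`frec.metrics` turns into the Feature Retrieval
Cost.  Encoding events (new categorial features, category duplications,
marked-person matches, fixture-valued spill-over regions) are recorded
per region for the Feature Encoding Cost.

The engine is schema-scoped: it handles the cleft and declarative
schemata that the shipped paradigms (and user paradigms of the same
shape) instantiate; it is not a general-coverage parser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

from .features import (
    AssignmentTable,
    CueConfig,
    DPTemplate,
    DPType,
    LexicalItem,
    Probe,
    distinctive_cue_count,
    dp_encoding_features,
    retrieval_feature_count,
)

__all__ = [
    "RegionId",
    "Region",
    "MemoryItem",
    "MergeEvent",
    "StoreEvent",
    "RetrieveEvent",
    "EncodeEvent",
    "DerivationTrace",
    "DerivationError",
    "IncompleteDerivationError",
    "UnretrievedFillerError",
    "derive",
    "trace_to_retrievals",
]


class RegionId(str, Enum):
    """Sentence regions.  The cleft schema uses BE < DP1 < C < DP2 < VERB <
    SPILL; OBJ is the in-situ object slot of the declarative schema."""

    BE = "BE"
    DP1 = "DP1"
    C = "C"
    DP2 = "DP2"
    VERB = "VERB"
    OBJ = "OBJ"
    SPILL = "SPILL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the canonical cleft region order
CLEFT_REGION_ORDER = (
    RegionId.BE,
    RegionId.DP1,
    RegionId.C,
    RegionId.DP2,
    RegionId.VERB,
    RegionId.SPILL,
)


@dataclass(frozen=True)
class Region:
    """One segmented region: its surface text, grammar tokens, and — for DP
    regions — the featural template of the phrase.  ``fixed_fec`` holds the
    paradigm's fixture-valued encoding cost (spill-over adjuncts)."""

    id: RegionId
    text: str
    tokens: tuple[LexicalItem, ...]
    dp: DPTemplate | None = None
    fixed_fec: int | None = None


@dataclass(frozen=True)
class MemoryItem:
    """A stored filler: its template, the categorial feature that was
    unselected at merge time, and where it was stored."""

    template: DPTemplate
    pending_category: str
    stored_at: RegionId


@dataclass(frozen=True)
class MergeEvent:
    region: RegionId
    form: str
    category: str
    kind: str = "merge"


@dataclass(frozen=True)
class StoreEvent:
    region: RegionId
    template: DPTemplate
    pending_category: str
    kind: str = "store"


@dataclass(frozen=True)
class RetrieveEvent:
    """One memory retrieval: the atoms of the Feature Retrieval Cost."""

    region: RegionId
    target: DPTemplate
    m: int
    n_f: int
    d_f: int
    probe: Probe
    kind: str = "retrieve"


@dataclass(frozen=True)
class EncodeEvent:
    """One encoding contribution.  ``rule`` names the encoding rule whose
    weight applies (``new_feature``, ``duplicated_category``,
    ``speech_act_participant``, ``person_match``); ``fixture`` carries its
    value directly."""

    region: RegionId
    feature: str
    rule: str
    value: int | None = None
    kind: str = "encode"


Event = MergeEvent | StoreEvent | RetrieveEvent | EncodeEvent


class DerivationError(ValueError):
    """A derivation failure, tagged with the offending region."""

    def __init__(self, message: str, region: RegionId | None = None):
        super().__init__(message)
        self.region = region


class IncompleteDerivationError(DerivationError):
    """Input ended with select-feature expectations still open."""


class UnretrievedFillerError(DerivationError):
    """A stored item was never re-merged by a matching select feature."""


@dataclass(frozen=True)
class DerivationTrace:
    """Ordered record of merge / store / retrieve / encode events."""

    label: str
    events: tuple[Event, ...]

    def retrievals(self, region: RegionId | None = None) -> tuple[RetrieveEvent, ...]:
        return tuple(
            e
            for e in self.events
            if isinstance(e, RetrieveEvent) and (region is None or e.region == region)
        )

    def stores(self) -> tuple[StoreEvent, ...]:
        return tuple(e for e in self.events if isinstance(e, StoreEvent))

    def encodes(self, region: RegionId | None = None) -> tuple[EncodeEvent, ...]:
        return tuple(
            e
            for e in self.events
            if isinstance(e, EncodeEvent) and (region is None or e.region == region)
        )

    # -- export ----------------------------------------------------------
    def to_jsonl(self) -> str:
        """One JSON object per event."""
        lines = []
        for e in self.events:
            rec: dict = {"region": e.region.value, "event": e.kind}
            if isinstance(e, MergeEvent):
                rec.update(form=e.form, category=e.category)
            elif isinstance(e, StoreEvent):
                rec.update(template=e.template.label or e.template.dp_type.value,
                           pending=e.pending_category)
            elif isinstance(e, RetrieveEvent):
                rec.update(target=e.target.label or e.target.dp_type.value,
                           m=e.m, nF=e.n_f, dF=e.d_f)
            elif isinstance(e, EncodeEvent):
                rec.update(feature=e.feature, rule=e.rule)
                if e.value is not None:
                    rec["value"] = e.value
            lines.append(json.dumps(rec, ensure_ascii=False))
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        """Human-readable indented derivation listing."""
        out = [f"derivation: {self.label}"]
        step = 0
        for e in self.events:
            if isinstance(e, MergeEvent):
                step += 1
                out.append(f"  {step}. [{e.region}] merge [{e.category} {e.form}]")
            elif isinstance(e, StoreEvent):
                out.append(
                    f"       store  <{e.pending_category} "
                    f"{e.template.label or e.template.dp_type.value}>  (unselected)"
                )
            elif isinstance(e, RetrieveEvent):
                out.append(
                    f"       retrieve {e.target.label or e.target.dp_type.value}"
                    f"  (m={e.m}, nF={e.n_f}, dF={e.d_f})"
                )
            elif isinstance(e, EncodeEvent):
                val = e.value if e.value is not None else e.rule
                out.append(f"       encode {e.feature} [{val}] in {e.region}")
        return "\n".join(out) + "\n"


#: categories whose unselected merge triggers storage (arguments)
_STORABLE = ("D",)


def derive(
    regions: Sequence[Region],
    cue: CueConfig,
    table: AssignmentTable,
    *,
    label: str = "",
) -> DerivationTrace:
    """Run the top-down derivation over a region-segmented sentence.

    Pure function of its inputs: identical regions and configurations
    yield identical traces.  Raises :class:`IncompleteDerivationError` if
    expectations remain open at the end of input and
    :class:`UnretrievedFillerError` if a stored item is never retrieved.
    """
    expectations: list[str] = []  # stack; top = last element
    buffer: list[MemoryItem] = []
    events: list[Event] = []
    merged_any = False
    dp1_template: DPTemplate | None = None
    last_region: RegionId | None = None

    for region in regions:
        last_region = region.id
        for token in region.tokens:
            outer = token.categories[0]
            if expectations and expectations[-1] == outer:
                expectations.pop()
                events.append(MergeEvent(region.id, token.form, outer))
            elif not merged_any or not expectations:
                # root merge, or right-adjunction to a completed clause
                events.append(MergeEvent(region.id, token.form, outer))
            elif outer in _STORABLE and region.dp is not None:
                # unselected argument: merge and store a copy in memory
                events.append(MergeEvent(region.id, token.form, outer))
                buffer.append(MemoryItem(region.dp, outer, region.id))
                events.append(StoreEvent(region.id, region.dp, outer))
            else:
                raise DerivationError(
                    f"unexpected category {outer!r} at region {region.id}"
                    f" (expected {expectations[-1]!r})",
                    region=region.id,
                )
            merged_any = True

            # expand select features in lexical order; a select satisfied
            # from the buffer is a retrieval, otherwise it projects an
            # expectation for new input
            to_expect: list[str] = []
            for sel in token.selects:
                indices = [
                    i for i, it in enumerate(buffer) if it.pending_category == sel.category
                ]
                if indices:
                    idx = indices[-1]  # most recently stored first
                    m = len(buffer)  # target included, counted before removal
                    item = buffer.pop(idx)
                    competitors = tuple(it.template for it in buffer)
                    probe = Probe.for_select(token, sel)
                    n_f = retrieval_feature_count(item.template, competitors, probe, cue, table)
                    d_f = distinctive_cue_count(item.template, competitors, probe, cue)
                    events.append(
                        RetrieveEvent(region.id, item.template, m, n_f, d_f, probe)
                    )
                else:
                    to_expect.append(sel.category)
            expectations.extend(reversed(to_expect))

        # region-level encoding contributions
        events.extend(_encode_region(region, dp1_template, cue))
        if region.id is RegionId.DP1 and region.dp is not None:
            dp1_template = region.dp

    if expectations:
        raise IncompleteDerivationError(
            f"incomplete derivation: open expectations {expectations[::-1]} at end of input",
            region=last_region,
        )
    if buffer:
        forms = [it.template.label or it.template.dp_type.value for it in buffer]
        raise UnretrievedFillerError(
            f"unretrieved filler(s): {forms}", region=buffer[0].stored_at
        )
    return DerivationTrace(label=label, events=tuple(events))


def _encode_region(
    region: Region, dp1: DPTemplate | None, cue: CueConfig
) -> Iterator[EncodeEvent]:
    """Encoding events for one region.

    Fixture-valued regions (spill-over adjuncts) carry their paradigm
    constant.  DP regions encode their template's new features, with two
    context adjustments at the second DP: a duplicated lexical restriction
    is re-encoded at the duplication weight, and a marked-person match
    with the first DP adds one unit.  Other regions encode one unit per
    categorial feature of their tokens (e.g. T and V at the verb).
    """
    if region.fixed_fec is not None:
        yield EncodeEvent(region.id, "fixture", "fixture", value=region.fixed_fec)
        return
    if region.dp is not None:
        # weights are resolved by the metrics layer; pass a unit table here
        # purely to enumerate the features.
        base = dp_encoding_features(region.dp, AssignmentTable())
        duplicated = (
            region.id is RegionId.DP2
            and dp1 is not None
            and region.dp.restriction is not None
            and region.dp.restriction == dp1.restriction
        )
        for feature, _ in base:
            rule = "new_feature"
            if feature.kind == "salient_index":
                rule = "speech_act_participant"
            elif duplicated and feature.value == region.dp.restriction:
                rule = "duplicated_category"
            yield EncodeEvent(region.id, feature.value, rule)
        if (
            region.id is RegionId.DP2
            and dp1 is not None
            and region.dp.person == dp1.person
            and region.dp.person in cue.marked_persons
        ):
            yield EncodeEvent(region.id, f"person:{region.dp.person}", "person_match")
        return
    for token in region.tokens:
        for category in token.categories:
            yield EncodeEvent(region.id, category, "new_feature")


def trace_to_retrievals(trace: DerivationTrace, region: RegionId) -> tuple[RetrieveEvent, ...]:
    """Ordered retrieval events of ``trace`` at ``region``."""
    if not isinstance(region, RegionId):
        try:
            region = RegionId(region)
        except ValueError:
            raise DerivationError(f"unknown region id {region!r}") from None
    return trace.retrievals(region)
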
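"""Feature vocabulary, DP templates, lexical items and cue configurations.

The cost calculus implemented by this package treats a noun phrase as a
bundle of features: a categorial skeleton (a determiner D and, when a
lexical restriction is present, a nominal N), phi features (person,
number), overt case morphology, and a flag for whether the referent is
contextually salient (deictic pronouns, proper names).  Four DP types
cover the experimental paradigms:

``definite``
    a full definite description ("the lawyer"): D plus a lexical
    restriction N, default 3rd person, no contextual salience.
``proper``
    a proper name ("Dan"): a contextually salient D index coindexed with
    its nominal restriction.
``bare_pronoun``
    a deictic pronoun ("you", "we"): just a contextually salient D index,
    with an empty nominal restriction.
``restricted_pronoun``
    a pronominal determiner with an overt restriction ("voi banchieri",
    'you bankers'): D plus N, marked (1st/2nd) person, and — when uttered
    out of the blue — a speech-act participant that must be added to the
    common ground.

The two retrieval quantities defined here, ``nF`` (features to be
retrieved from memory) and ``dF`` (distinctive cued features), are the
per-event atoms of the Feature Retrieval Cost computed in
:mod:`frec.metrics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "DPType",
    "Feature",
    "DPTemplate",
    "SelectFeature",
    "LexicalItem",
    "Probe",
    "CueConfig",
    "AssignmentTable",
    "ConfigError",
    "dp_encoding_features",
    "retrieval_feature_count",
    "distinctive_cue_count",
]


class ConfigError(ValueError):
    """Raised for ill-formed cue/assignment configurations or templates."""


class DPType(str, Enum):
    DEFINITE = "definite"
    PROPER = "proper"
    BARE_PRONOUN = "bare_pronoun"
    RESTRICTED_PRONOUN = "restricted_pronoun"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: feature kinds recognised by the calculus
FEATURE_KINDS = (
    "categorial",
    "select",
    "person",
    "number",
    "case",
    "salient_index",
)


@dataclass(frozen=True)
class Feature:
    """An atomic feature: a kind and a symbolic value (e.g. categorial D)."""

    kind: str
    value: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ConfigError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class DPTemplate:
    """Featural specification of a noun-phrase type.

    ``case_overt`` marks visible case morphology on the item itself
    (English "we" is overtly nominative; "you" and full DPs carry no case
    morphology).  ``out_of_the_blue`` marks the absence of a licensing
    context for a pronominal determiner, which forces the hearer to accommodate
    a speech-act participant into the restriction.
    """

    dp_type: DPType
    person: int = 3
    number: str = "pl"
    case_overt: bool = False
    case: str | None = None
    out_of_the_blue: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.person not in (1, 2, 3):
            raise ConfigError(f"person must be 1, 2 or 3, got {self.person}")
        if self.number not in ("sg", "pl"):
            raise ConfigError(f"number must be 'sg' or 'pl', got {self.number!r}")
        if self.dp_type is DPType.RESTRICTED_PRONOUN and self.person == 3:
            raise ConfigError(
                "a restricted pronoun bears marked (1st/2nd) person; got person 3"
            )
        if self.case_overt and self.case is None:
            raise ConfigError("case_overt requires an explicit case value")

    @property
    def has_salient_index(self) -> bool:
        """Whether the D layer is a contextually salient index (pronouns, names)."""
        return self.dp_type is not DPType.DEFINITE

    @property
    def has_index_shortcut(self) -> bool:
        """Whether retrieval can ride on the salient index alone.

        Proper names and bare pronouns are retrieved through their salient
        D index, which is what makes their base retrieval load lighter than
        a full description's; the shortcut is lost when a same-person
        salient competitor sits in the buffer.  Restricted pronouns carry a
        full lexical restriction and never use the shortcut.
        """
        return self.dp_type in (DPType.PROPER, DPType.BARE_PRONOUN)

    @property
    def restriction(self) -> str | None:
        """Category of the lexical restriction (N, N_prop) or None if empty."""
        if self.dp_type in (DPType.DEFINITE, DPType.RESTRICTED_PRONOUN):
            return "N"
        if self.dp_type is DPType.PROPER:
            return "N_prop"
        return None


@dataclass(frozen=True)
class SelectFeature:
    """A select feature =X: the category expected next, with the case the
    position assigns and whether the selecting head's agreement probes it."""

    category: str
    case: str | None = None
    agrees: bool = False


@dataclass(frozen=True)
class LexicalItem:
    """A grammar entry: surface form, categorial features (outermost first),
    ordered select features, and the phi features its agreement probes."""

    form: str
    categories: tuple[str, ...]
    selects: tuple[SelectFeature, ...] = ()
    agreement: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.categories:
            raise ConfigError(f"lexical item {self.form!r} has no category")


@dataclass(frozen=True)
class Probe:
    """The retrieval cue active at one select-feature expansion.

    A finite agreeing verb probes person/number on its subject slot only;
    the object slot (and every slot of an English past-tense verb) probes
    nothing.  ``case`` is the case the position assigns, usable as a cue
    when the retrieved item is case-overt.
    """

    agreement: frozenset[str] = frozenset()
    case: str | None = None

    @classmethod
    def for_select(cls, item: LexicalItem, select: SelectFeature) -> "Probe":
        agr = item.agreement if select.agrees else frozenset()
        return cls(agreement=agr, case=select.case)


def _as_set(values: Iterable) -> frozenset:
    return frozenset(values)


@dataclass(frozen=True)
class CueConfig:
    """Which features a verbal probe treats as distinctive retrieval cues.

    ``hypothesis`` H1 counts any cued person mismatch as distinctive; H2
    restricts the facilitation to marked (speech-act anchored) persons, so
    a 3rd-person target never earns a person cue.
    """

    hypothesis: str = "H2"
    probe_features_at_verb: frozenset[str] = frozenset({"person", "number"})
    case_cue: bool = False
    marked_persons: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H1", "H2"):
            raise ConfigError(f"hypothesis must be 'H1' or 'H2', got {self.hypothesis!r}")
        object.__setattr__(self, "probe_features_at_verb", _as_set(self.probe_features_at_verb))
        object.__setattr__(self, "marked_persons", _as_set(int(p) for p in self.marked_persons))
        bad = self.probe_features_at_verb - {"person", "number"}
        if bad:
            raise ConfigError(f"unknown probe features: {sorted(bad)}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "probeFeaturesAtVerb": sorted(self.probe_features_at_verb),
            "caseCue": self.case_cue,
            "markedPersons": sorted(self.marked_persons),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CueConfig":
        return cls(
            hypothesis=data.get("hypothesis", "H2"),
            probe_features_at_verb=frozenset(data.get("probeFeaturesAtVerb", ["person", "number"])),
            case_cue=bool(data.get("caseCue", False)),
            marked_persons=frozenset(data.get("markedPersons", [1, 2])),
        )

    @classmethod
    def english(cls) -> "CueConfig":
        """Past-tense cleft predicate: no phi probe, but overt case morphology
        on pronouns is usable as a cue (nominative "we" vs "us")."""
        return cls(hypothesis="H2", probe_features_at_verb=frozenset(), case_cue=True)

    @classmethod
    def italian(cls, hypothesis: str = "H2") -> "CueConfig":
        """Finite agreeing predicate probing person and number; Italian DPs
        carry no case morphology."""
        return cls(
            hypothesis=hypothesis,
            probe_features_at_verb=frozenset({"person", "number"}),
            case_cue=False,
        )


_DEFAULT_BASE_NF = {
    DPType.DEFINITE: 2,
    DPType.PROPER: 1,
    DPType.BARE_PRONOUN: 1,
    DPType.RESTRICTED_PRONOUN: 2,
}

_DEFAULT_ENCODING_WEIGHTS = {
    "new_feature": 1,
    "duplicated_category": 2,
    "salient": 0,
    "speech_act_participant": 1,
    "person_match": 1,
}


@dataclass(frozen=True)
class AssignmentTable:
    """Per-DP-type feature loads: the nF/eF weights of the cost calculus.

    ``base_nf`` is the number of features a retrieval of each DP type must
    recover from memory; a full description costs its D and N (2), while
    salient-index types ride the index (1).  ``person_nf_bonus`` is added
    when an agreement-bearing probe retrieves a marked-person target (the
    marked person feature is one more thing to recover).
    ``confusability_nf_bonus`` is added when the salient-index shortcut is
    lost because another same-person salient item sits in the buffer.
    """

    base_nf: Mapping[DPType, int] = field(default_factory=lambda: dict(_DEFAULT_BASE_NF))
    person_nf_bonus: int = 1
    confusability_nf_bonus: int = 1
    encoding_weights: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_ENCODING_WEIGHTS)
    )

    def __post_init__(self) -> None:
        base = {DPType(k): int(v) for k, v in dict(self.base_nf).items()}
        object.__setattr__(self, "base_nf", base)
        weights = {str(k): int(v) for k, v in dict(self.encoding_weights).items()}
        object.__setattr__(self, "encoding_weights", weights)
        for name, value in [("person_nf_bonus", self.person_nf_bonus),
                            ("confusability_nf_bonus", self.confusability_nf_bonus)]:
            if value < 0:
                raise ConfigError(f"{name} must be non-negative, got {value}")
        if any(v < 0 for v in base.values()) or any(v < 0 for v in weights.values()):
            raise ConfigError("all assignment-table weights must be non-negative")

    def weight(self, rule: str) -> int:
        try:
            return self.encoding_weights[rule]
        except KeyError:
            raise ConfigError(f"unknown encoding rule {rule!r}") from None

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseNF": {t.value: v for t, v in self.base_nf.items()},
            "personNFBonus": self.person_nf_bonus,
            "confusabilityNFBonus": self.confusability_nf_bonus,
            "encodingWeights": dict(self.encoding_weights),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AssignmentTable":
        kwargs = {}
        if "baseNF" in data:
            kwargs["base_nf"] = {DPType(k): v for k, v in data["baseNF"].items()}
        if "personNFBonus" in data:
            kwargs["person_nf_bonus"] = data["personNFBonus"]
        if "confusabilityNFBonus" in data:
            kwargs["confusability_nf_bonus"] = data["confusabilityNFBonus"]
        if "encodingWeights" in data:
            weights = dict(_DEFAULT_ENCODING_WEIGHTS)
            weights.update(data["encodingWeights"])
            kwargs["encoding_weights"] = weights
        return cls(**kwargs)


def _load_document(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_cue_config(path: str | Path) -> CueConfig:
    """Read a :class:`CueConfig` from a flat JSON or YAML document."""
    return CueConfig.from_dict(_load_document(path))


def load_assignment_table(path: str | Path) -> AssignmentTable:
    """Read an :class:`AssignmentTable` from a flat JSON or YAML document."""
    return AssignmentTable.from_dict(_load_document(path))


def save_config(obj: CueConfig | AssignmentTable, path: str | Path) -> None:
    path = Path(path)
    data = obj.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# operations


def dp_encoding_features(
    template: DPTemplate, table: AssignmentTable
) -> tuple[tuple[Feature, int], ...]:
    """New features a freshly merged DP must encode, with per-feature weights.

    Context-free view: a definite description pays for its D and its N; a
    proper name pays only for its nominal restriction (the salient D index
    is free); a deictic pronoun pays nothing (already pre-activated in the
    context); a restricted pronoun pays D and N plus, out of the blue, the
    accommodation of a speech-act participant.  Context-dependent
    adjustments (category duplication, marked-person match) are applied by
    the derivation engine at the second DP.
    """
    w_new = table.weight("new_feature")
    w_sap = table.weight("speech_act_participant")
    t = template.dp_type
    if t is DPType.DEFINITE:
        return (
            (Feature("categorial", "D"), w_new),
            (Feature("categorial", "N"), w_new),
        )
    if t is DPType.PROPER:
        # the salient D index is free; the name's restriction costs one unit
        return ((Feature("categorial", "N_prop"), w_new),)
    if t is DPType.BARE_PRONOUN:
        return ()
    if t is DPType.RESTRICTED_PRONOUN:
        out: list[tuple[Feature, int]] = [
            (Feature("categorial", "D"), w_new),
            (Feature("categorial", "N"), w_new),
        ]
        if template.out_of_the_blue:
            out.append((Feature("salient_index", "speech_act_participant"), w_sap))
        return tuple(out)
    raise ConfigError(f"unknown DP type {t!r}")  # pragma: no cover


def retrieval_feature_count(
    target: DPTemplate,
    competitors: Sequence[DPTemplate],
    probe: Probe,
    cue: CueConfig,
    table: AssignmentTable,
) -> int:
    """nF — number of features a retrieval of ``target`` must recover.

    ``competitors`` are the other items in the memory buffer at the moment
    of retrieval (target excluded).  The base load depends on DP type; an
    agreement-bearing probe adds the marked-person feature; and a
    salient-index target loses its retrieval shortcut when a same-person
    salient competitor is present (confusability).
    """
    nf = table.base_nf[target.dp_type]
    if "person" in probe.agreement and target.person in cue.marked_persons:
        nf += table.person_nf_bonus
    if target.has_index_shortcut and any(
        c.has_salient_index and c.person == target.person for c in competitors
    ):
        nf += table.confusability_nf_bonus
    return nf


def distinctive_cue_count(
    target: DPTemplate,
    competitors: Sequence[DPTemplate],
    probe: Probe,
    cue: CueConfig,
) -> int:
    """dF — number of cued feature dimensions that single out the target.

    A dimension counts only if the probe cues it, the cue configuration
    admits it, and the target's value differs from every competitor's.
    Under H2 a person difference counts only for marked-person targets;
    case counts only when the target itself is case-overt and no competitor
    could match the cued case form.  With no competitors there is nothing
    to be distinct from and dF is 0.
    """
    if not competitors:
        return 0
    df = 0
    dims = probe.agreement & cue.probe_features_at_verb
    if "person" in dims:
        admissible = cue.hypothesis == "H1" or target.person in cue.marked_persons
        if admissible and all(c.person != target.person for c in competitors):
            df += 1
    if "number" in dims:
        if all(c.number != target.number for c in competitors):
            df += 1
    if cue.case_cue and probe.case is not None:
        if (
            target.case_overt
            and target.case == probe.case
            and not any(c.case_overt and c.case == probe.case for c in competitors)
        ):
            df += 1
    return df
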
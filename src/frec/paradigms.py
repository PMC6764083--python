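"""Experimental paradigms: built-in fixtures and a small TSV/JSON dialect.

Two paradigms ship with the package.  The English object-cleft paradigm
crosses definite description (D), proper name (N) and bare pronoun (P)
over the focalized-object and cleft-subject positions (3x3, "It was the
banker that the lawyer avoided at the party"), with the published
self-paced-reading means attached.  The Italian paradigm crosses plural
definite articles (Art, "i banchieri") with 2nd-person-plural pronominal
determiners (Pro, "voi banchieri") over the same two positions (2x2),
probed by an overtly agreeing finite verb.  Costs depend only on the
featural templates, so one schematic item per condition suffices.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

from .derivation import Region, RegionId
from .features import DPTemplate, DPType, LexicalItem, SelectFeature

__all__ = [
    "Condition",
    "Paradigm",
    "ReadingTimeTable",
    "ParadigmFormatError",
    "english_paradigm",
    "italian_paradigm",
    "make_cleft_condition",
    "make_subject_cleft_condition",
    "make_declarative_condition",
    "load_paradigm",
    "save_paradigm",
]


class ParadigmFormatError(ValueError):
    """Malformed paradigm file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a region-segmented sentence with DP
    annotations plus the paradigm's fixture-valued spill costs."""

    label: str
    language: str
    regions: tuple[Region, ...]
    spill_fec: int
    dlt_spill: int

    @property
    def dp1(self) -> DPTemplate | None:
        return next((r.dp for r in self.regions if r.id is RegionId.DP1), None)

    @property
    def dp2(self) -> DPTemplate | None:
        return next((r.dp for r in self.regions if r.id is RegionId.DP2), None)

    def region(self, region_id: RegionId) -> Region:
        for r in self.regions:
            if r.id is region_id:
                return r
        raise KeyError(region_id)


@dataclass(frozen=True)
class ReadingTimeTable:
    """Published mean reading times (ms) with standard errors, by condition."""

    times: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        times = {str(k): (int(v[0]), int(v[1])) for k, v in dict(self.times).items()}
        if any(mean <= 0 for mean, _ in times.values()):
            raise ParadigmFormatError("reading times must be positive")
        object.__setattr__(self, "times", times)

    def mean(self, label: str) -> int:
        return self.times[label][0]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.times)


@dataclass(frozen=True)
class Paradigm:
    """A named set of conditions, optionally with attached reading times."""

    name: str
    language: str
    conditions: tuple[Condition, ...]
    reading_times: ReadingTimeTable | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ParadigmFormatError(f"duplicate condition labels in {self.name!r}")

    def condition(self, label: str) -> Condition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)


# ---------------------------------------------------------------------------
# grammar construction

_SPILL_FEC = {"english": 3, "italian": 5}
_DLT_SPILL = 4


def _dp_tokens(template: DPTemplate, text: str) -> tuple[LexicalItem, ...]:
    """Grammar tokens for a DP: the D head (selecting its restriction) plus
    the restriction itself — an overt noun, a name's coindexed trace, or a
    pronoun's empty N."""
    words = text.split()
    head = words[0]
    rest = " ".join(words[1:])
    sel_n = (SelectFeature("N"),)
    if template.dp_type is DPType.DEFINITE:
        return (
            LexicalItem(head, ("D",), sel_n),
            LexicalItem(rest or "N", ("N",)),
        )
    if template.dp_type is DPType.PROPER:
        return (
            LexicalItem(text, ("D",), sel_n),
            LexicalItem("<t>", ("N",)),
        )
    if template.dp_type is DPType.BARE_PRONOUN:
        return (
            LexicalItem(text, ("D",), sel_n),
            LexicalItem("<e>", ("N",)),
        )
    # restricted pronoun: pronominal determiner + overt restriction
    return (
        LexicalItem(head, ("D",), sel_n),
        LexicalItem(rest or "N", ("N",)),
    )


def _verb_token(text: str, language: str) -> LexicalItem:
    """The cleft predicate: categories T and V; subject (nominative,
    agreement-bearing) select expanded before the object select.  The
    English past-tense form carries no phi probe; the Italian finite form
    probes person and number."""
    agreement = frozenset({"person", "number"}) if language == "italian" else frozenset()
    return LexicalItem(
        text,
        ("T", "V"),
        (
            SelectFeature("D", case="nom", agrees=True),
            SelectFeature("D", case="acc", agrees=False),
        ),
        agreement=agreement,
    )


def _spill_tokens(text: str) -> tuple[LexicalItem, ...]:
    words = text.split()
    head = words[0] if words else "P"
    rest = words[1:]
    tokens = [LexicalItem(head, ("P",), (SelectFeature("D"),))]
    if rest:
        tokens.append(LexicalItem(rest[0], ("D",), (SelectFeature("N"),)))
        tokens.append(LexicalItem(" ".join(rest[1:]) or "N", ("N",)))
    return tuple(tokens)


def make_cleft_condition(
    label: str,
    language: str,
    texts: Mapping[str, str],
    dp1: DPTemplate,
    dp2: DPTemplate,
    spill_fec: int | None = None,
    dlt_spill: int = _DLT_SPILL,
) -> Condition:
    """Build an object-cleft condition from region texts and DP templates.

    ``texts`` maps region ids (BE, DP1, C, DP2, VERB, SPILL) to surface
    strings.  The grammar tokens are generated from the templates, so two
    conditions with identical texts and templates compare equal.
    """
    if spill_fec is None:
        spill_fec = _SPILL_FEC.get(language, 3)
    regions = (
        Region(RegionId.BE, texts["BE"], (LexicalItem(texts["BE"], ("Cop",), (SelectFeature("C"),)),)),
        Region(RegionId.DP1, texts["DP1"], _dp_tokens(dp1, texts["DP1"]), dp=dp1),
        Region(RegionId.C, texts["C"], (LexicalItem(texts["C"], ("C",), (SelectFeature("T"),)),)),
        Region(RegionId.DP2, texts["DP2"], _dp_tokens(dp2, texts["DP2"]), dp=dp2),
        Region(RegionId.VERB, texts["VERB"], (_verb_token(texts["VERB"], language),)),
        Region(RegionId.SPILL, texts["SPILL"], _spill_tokens(texts["SPILL"]), fixed_fec=spill_fec),
    )
    return Condition(label, language, regions, spill_fec, dlt_spill)


def make_subject_cleft_condition(
    label: str,
    language: str,
    texts: Mapping[str, str],
    dp1: DPTemplate,
    obj: DPTemplate,
    spill_fec: int | None = None,
    dlt_spill: int = _DLT_SPILL,
) -> Condition:
    """A subject cleft: the focalized DP is the subject and the object
    stays in situ after the verb, so only one item is ever stored and
    retrieved (m = 1)."""
    if spill_fec is None:
        spill_fec = _SPILL_FEC.get(language, 3)
    regions = (
        Region(RegionId.BE, texts["BE"], (LexicalItem(texts["BE"], ("Cop",), (SelectFeature("C"),)),)),
        Region(RegionId.DP1, texts["DP1"], _dp_tokens(dp1, texts["DP1"]), dp=dp1),
        Region(RegionId.C, texts["C"], (LexicalItem(texts["C"], ("C",), (SelectFeature("T"),)),)),
        Region(RegionId.VERB, texts["VERB"], (_verb_token(texts["VERB"], language),)),
        Region(RegionId.OBJ, texts["OBJ"], _dp_tokens(obj, texts["OBJ"]), dp=obj),
        Region(RegionId.SPILL, texts["SPILL"], _spill_tokens(texts["SPILL"]), fixed_fec=spill_fec),
    )
    return Condition(label, language, regions, spill_fec, dlt_spill)


def make_declarative_condition(
    label: str,
    language: str,
    subject_text: str,
    subject: DPTemplate,
    verb_text: str,
    object_text: str,
    obj: DPTemplate,
) -> Condition:
    """A canonical SVO declarative with no displacement: the subject roots
    the clause and selects the predicate, whose object select is satisfied
    by new input, so nothing is ever stored or retrieved."""
    subj_tokens = list(_dp_tokens(subject, subject_text))
    head = subj_tokens[0]
    subj_tokens[0] = replace(head, selects=head.selects + (SelectFeature("V"),))
    verb = LexicalItem(verb_text, ("V",), (SelectFeature("D", case="acc"),))
    regions = (
        Region(RegionId.DP2, subject_text, tuple(subj_tokens), dp=subject),
        Region(RegionId.VERB, verb_text, (verb,)),
        Region(RegionId.OBJ, object_text, _dp_tokens(obj, object_text), dp=obj),
    )
    return Condition(label, language, regions, spill_fec=0, dlt_spill=0)


# ---------------------------------------------------------------------------
# built-in fixtures


def _definite(text: str) -> DPTemplate:
    return DPTemplate(DPType.DEFINITE, person=3, number="sg", label=text)


def _proper(text: str) -> DPTemplate:
    return DPTemplate(DPType.PROPER, person=3, number="sg", label=text)


_ENGLISH_RTS = {
    "D1-D2": (365, 19),
    "D1-N2": (319, 12),
    "D1-P2": (306, 14),
    "N1-D2": (348, 18),
    "N1-N2": (347, 21),
    "N1-P2": (291, 14),
    "P1-D2": (348, 18),
    "P1-N2": (311, 15),
    "P1-P2": (291, 13),
}


def english_paradigm() -> Paradigm:
    """The 3x3 English object-cleft paradigm with its published mean
    self-paced reading times at the verb attached.  Fresh objects on every
    call; mutation never leaks across calls."""
    dp1_specs = {
        "D1": ("the banker", _definite("the banker")),
        "N1": ("Patricia", _proper("Patricia")),
        "P1": ("you", DPTemplate(DPType.BARE_PRONOUN, person=2, number="pl", label="you")),
    }
    dp2_specs = {
        "D2": ("the lawyer", _definite("the lawyer")),
        "N2": ("Dan", _proper("Dan")),
        "P2": (
            "we",
            DPTemplate(
                DPType.BARE_PRONOUN, person=1, number="pl",
                case_overt=True, case="nom", label="we",
            ),
        ),
    }
    conditions = []
    for k1, (t1, dp1) in dp1_specs.items():
        for k2, (t2, dp2) in dp2_specs.items():
            label = f"{k1}-{k2}"
            texts = {
                "BE": "It was",
                "DP1": t1,
                "C": "that",
                "DP2": t2,
                "VERB": "avoided",
                "SPILL": "at the party",
            }
            conditions.append(make_cleft_condition(label, "english", texts, dp1, dp2))
    return Paradigm(
        name="english",
        language="english",
        conditions=tuple(conditions),
        reading_times=ReadingTimeTable(dict(_ENGLISH_RTS)),
    )


def italian_paradigm() -> Paradigm:
    """The 2x2 Italian paradigm: plural definite articles vs 2nd-person
    plural pronominal determiners, out of the blue, with overt subject-verb
    person/number agreement.  Number and gender are constant across DPs."""
    art1 = DPTemplate(DPType.DEFINITE, person=3, number="pl", label="i banchieri")
    pro1 = DPTemplate(
        DPType.RESTRICTED_PRONOUN, person=2, number="pl",
        out_of_the_blue=True, label="voi banchieri",
    )
    art2 = DPTemplate(DPType.DEFINITE, person=3, number="pl", label="gli avvocati")
    pro2 = DPTemplate(
        DPType.RESTRICTED_PRONOUN, person=2, number="pl",
        out_of_the_blue=True, label="voi avvocati",
    )
    specs = {
        "Art1-Art2": ("i banchieri", art1, "gli avvocati", art2, "hanno evitato"),
        "Art1-Pro2": ("i banchieri", art1, "voi avvocati", pro2, "avete evitato"),
        "Pro1-Art2": ("voi banchieri", pro1, "gli avvocati", art2, "hanno evitato"),
        "Pro1-Pro2": ("voi banchieri", pro1, "voi avvocati", pro2, "avete evitato"),
    }
    conditions = []
    for label, (t1, dp1, t2, dp2, verb) in specs.items():
        texts = {
            "BE": "Erano",
            "DP1": t1,
            "C": "che",
            "DP2": t2,
            "VERB": verb,
            "SPILL": "alla festa",
        }
        conditions.append(make_cleft_condition(label, "italian", texts, dp1, dp2))
    return Paradigm(name="italian", language="italian", conditions=tuple(conditions))


# ---------------------------------------------------------------------------
# TSV / JSON dialect

_TSV_COLUMNS = [
    "label", "language",
    "be", "dp1", "c", "dp2", "verb", "spill",
    "dp1_type", "dp1_person", "dp1_number", "dp1_case_overt", "dp1_case", "dp1_out_of_the_blue",
    "dp2_type", "dp2_person", "dp2_number", "dp2_case_overt", "dp2_case", "dp2_out_of_the_blue",
    "spill_fec", "dlt_spill",
]

_VALID_TYPES = ", ".join(t.value for t in DPType)


def _template_to_row(prefix: str, t: DPTemplate) -> dict:
    return {
        f"{prefix}_type": t.dp_type.value,
        f"{prefix}_person": str(t.person),
        f"{prefix}_number": t.number,
        f"{prefix}_case_overt": str(t.case_overt).lower(),
        f"{prefix}_case": t.case or "",
        f"{prefix}_out_of_the_blue": str(t.out_of_the_blue).lower(),
    }


def _template_from_row(prefix: str, row: Mapping[str, str], label: str, line: int) -> DPTemplate:
    raw_type = row[f"{prefix}_type"].strip()
    try:
        dp_type = DPType(raw_type)
    except ValueError:
        raise ParadigmFormatError(
            f"unknown dpType {raw_type!r}; valid values: {_VALID_TYPES}", line=line
        ) from None
    try:
        return DPTemplate(
            dp_type,
            person=int(row[f"{prefix}_person"]),
            number=row[f"{prefix}_number"].strip(),
            case_overt=row[f"{prefix}_case_overt"].strip().lower() == "true",
            case=row[f"{prefix}_case"].strip() or None,
            out_of_the_blue=row[f"{prefix}_out_of_the_blue"].strip().lower() == "true",
            label=label,
        )
    except (ValueError, KeyError) as exc:
        raise ParadigmFormatError(str(exc), line=line) from None


def _condition_to_row(c: Condition) -> dict:
    row = {
        "label": c.label,
        "language": c.language,
        "be": c.region(RegionId.BE).text,
        "dp1": c.region(RegionId.DP1).text,
        "c": c.region(RegionId.C).text,
        "dp2": c.region(RegionId.DP2).text,
        "verb": c.region(RegionId.VERB).text,
        "spill": c.region(RegionId.SPILL).text,
        "spill_fec": str(c.spill_fec),
        "dlt_spill": str(c.dlt_spill),
    }
    row.update(_template_to_row("dp1", c.dp1))
    row.update(_template_to_row("dp2", c.dp2))
    return row


def _condition_from_row(row: Mapping[str, str], line: int) -> Condition:
    missing = [col for col in _TSV_COLUMNS if col not in row or row[col] is None]
    if missing:
        raise ParadigmFormatError(f"missing columns: {missing}", line=line)
    dp1 = _template_from_row("dp1", row, row["dp1"].strip(), line)
    dp2 = _template_from_row("dp2", row, row["dp2"].strip(), line)
    texts = {
        "BE": row["be"].strip(),
        "DP1": row["dp1"].strip(),
        "C": row["c"].strip(),
        "DP2": row["dp2"].strip(),
        "VERB": row["verb"].strip(),
        "SPILL": row["spill"].strip(),
    }
    try:
        spill_fec = int(row["spill_fec"])
        dlt_spill = int(row["dlt_spill"])
    except ValueError as exc:
        raise ParadigmFormatError(str(exc), line=line) from None
    return make_cleft_condition(
        row["label"].strip(), row["language"].strip(), texts, dp1, dp2,
        spill_fec=spill_fec, dlt_spill=dlt_spill,
    )


def save_paradigm(paradigm: Paradigm, path: str | Path) -> None:
    """Write a paradigm as TSV (conditions only) or JSON (conditions plus
    attached reading times), chosen by file suffix."""
    path = Path(path)
    if path.suffix == ".json":
        doc: dict = {
            "name": paradigm.name,
            "language": paradigm.language,
            "conditions": [_condition_to_row(c) for c in paradigm.conditions],
        }
        if paradigm.reading_times is not None:
            doc["reading_times"] = {
                label: list(pair) for label, pair in paradigm.reading_times.times.items()
            }
        path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        return
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t")
        writer.writeheader()
        for c in paradigm.conditions:
            writer.writerow(_condition_to_row(c))


def load_paradigm(path: str | Path) -> Paradigm:
    """Read a paradigm from the TSV/JSON dialect written by
    :func:`save_paradigm`.  Malformed rows raise
    :class:`ParadigmFormatError` with the offending line number."""
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        conditions = tuple(
            _condition_from_row(row, line) for line, row in enumerate(doc["conditions"], start=1)
        )
        rts = None
        if doc.get("reading_times"):
            rts = ReadingTimeTable({k: tuple(v) for k, v in doc["reading_times"].items()})
        language = doc.get("language") or (conditions[0].language if conditions else "english")
        return Paradigm(doc.get("name", path.stem), language, conditions, reading_times=rts)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParadigmFormatError("empty paradigm file", line=1)
        unknown = [f for f in reader.fieldnames if f not in _TSV_COLUMNS]
        if unknown:
            raise ParadigmFormatError(f"unknown columns: {unknown}", line=1)
        conditions = tuple(
            _condition_from_row(row, line) for line, row in enumerate(reader, start=2)
        )
    if not conditions:
        raise ParadigmFormatError("paradigm has no conditions", line=2)
    return Paradigm(path.stem, conditions[0].language, conditions)
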
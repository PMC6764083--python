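"""Cost metrics: Feature Retrieval Cost, Feature Encoding Cost, combined
region profiles, and the dependency-locality (memory-load) baseline.

The Feature Retrieval Cost of a region x with retrievals i = 1..n is

    FRC(x) = prod_i (1 + nF_i)^(m_i) / (1 + dF_i)

i.e. it grows exponentially in the number of items stored in memory at
each retrieval (m), linearly in the number of features to be recovered
(nF), and is mitigated linearly by the number of distinctive cued
features (dF).  The product is kept in exact rational arithmetic; the
base-10 logarithm is applied only when reporting.

The Feature Encoding Cost of a region is the sum of per-feature weights
eF over the new features encoded there: 1 per new categorial feature, 2
for re-encoding a duplicated lexical category as a selected argument, 0
for contextually salient material, plus the restricted-pronoun and
marked-person-match increments.  The combined FREC profile scores DP
regions by FEC and the verb region by FEC(verb) + log10 FRC(verb).

The memory-load baseline scores each DP by the accessibility weight of
its discourse referent and the verb by an event-referent cost plus an
integration cost that crosses the verbal event and the intervening
subject referent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Sequence

from .derivation import (
    DerivationTrace,
    Region,
    RegionId,
    RetrieveEvent,
    derive,
)
from .features import AssignmentTable, ConfigError, CueConfig, DPType

__all__ = [
    "RegionCostProfile",
    "DltConfig",
    "frc",
    "log_frc",
    "fec",
    "frec_profile",
    "dlt_profile",
]


def frc(retrievals: Sequence[RetrieveEvent]) -> Fraction:
    """Feature Retrieval Cost of an ordered list of retrieval events.

    Exact rational product of (1+nF)^m / (1+dF); the empty product is 1
    (a region with no retrievals costs nothing to search).
    """
    total = Fraction(1)
    for event in retrievals:
        total *= Fraction((1 + event.n_f) ** event.m, 1 + event.d_f)
    return total


def log_frc(value: Fraction | int) -> float:
    """Base-10 log of an FRC value, rounded half-up to 2 decimals."""
    value = Fraction(value)
    if value <= 0:
        raise ValueError(f"FRC must be positive, got {value}")
    lg = math.log10(value.numerator) - math.log10(value.denominator)
    return float(Decimal(repr(lg)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fec(trace: DerivationTrace, region: RegionId, table: AssignmentTable) -> int:
    """Feature Encoding Cost of one region: sum of eF weights over the
    region's encoding events, resolved against ``table`` (fixture-valued
    regions carry their paradigm constant directly)."""
    total = 0
    for event in trace.encodes(region):
        total += event.value if event.value is not None else table.weight(event.rule)
    return total


@dataclass(frozen=True)
class RegionCostProfile:
    """Per-region cost values for one condition: the rows of the prediction
    grids.  ``frc_value`` is exact; ``frec_verb`` = FEC(verb) + log10 FRC."""

    label: str
    fec: Mapping[RegionId, int] = field(default_factory=dict)
    frc_value: Fraction = Fraction(1)
    frec_verb: float | None = None
    dlt: Mapping[RegionId, float] = field(default_factory=dict)

    @property
    def log_frc(self) -> float:
        return log_frc(self.frc_value)


def frec_profile(condition, cue: CueConfig, table: AssignmentTable) -> RegionCostProfile:
    """Full FREC profile of a condition: derives it, scores every region's
    FEC, and combines encoding and retrieval cost at the verb."""
    trace = derive(condition.regions, cue, table, label=condition.label)
    fec_by_region = {r.id: fec(trace, r.id, table) for r in condition.regions}
    verb_frc = frc(trace.retrievals(RegionId.VERB))
    frec_verb = None
    if RegionId.VERB in fec_by_region:
        frec_verb = round(fec_by_region[RegionId.VERB] + log_frc(verb_frc), 2)
    return RegionCostProfile(
        label=condition.label,
        fec=fec_by_region,
        frc_value=verb_frc,
        frec_verb=frec_verb,
    )


_A1_WEIGHTS = {t: 2 for t in DPType}
_A2_WEIGHTS = {
    DPType.DEFINITE: 3,
    DPType.PROPER: 1,
    DPType.BARE_PRONOUN: 0,
    DPType.RESTRICTED_PRONOUN: 2,
}
_A3_WEIGHTS = {
    DPType.DEFINITE: 2,
    DPType.PROPER: 1,
    DPType.BARE_PRONOUN: 0,
    DPType.RESTRICTED_PRONOUN: 3,
}


@dataclass(frozen=True)
class DltConfig:
    """Accessibility weighting for the memory-load baseline.

    A1 treats article-DPs and pronominal-determiner DPs as referentially
    alike (all weights equal); A2 makes the article-DP the less accessible
    referent; A3 makes the restricted pronoun the less accessible one
    (accommodating a speech-act participant out of the blue).  The verb
    introduces an event referent and pays an integration cost crossing the
    verbal event plus the intervening subject referent.
    """

    assumption: str = "A3"
    referent_weight: Mapping[DPType, int] = field(default_factory=lambda: dict(_A3_WEIGHTS))
    event_referent_cost: int = 1
    crossing_cost: int = 1

    def __post_init__(self) -> None:
        if self.assumption not in ("A1", "A2", "A3"):
            raise ConfigError(f"unknown accessibility assumption {self.assumption!r}")
        object.__setattr__(
            self,
            "referent_weight",
            {DPType(k): int(v) for k, v in dict(self.referent_weight).items()},
        )

    @classmethod
    def for_assumption(cls, assumption: str) -> "DltConfig":
        weights = {"A1": _A1_WEIGHTS, "A2": _A2_WEIGHTS, "A3": _A3_WEIGHTS}
        if assumption not in weights:
            raise ConfigError(f"unknown accessibility assumption {assumption!r}")
        return cls(assumption=assumption, referent_weight=dict(weights[assumption]))


def dlt_profile(condition, cfg: DltConfig | None = None) -> RegionCostProfile:
    """Memory-load (dependency-locality) profile of a condition.

    DP regions cost the accessibility weight of their referent; the verb
    costs event referent + crossing + intervening-subject weight; the
    spill-over region carries the paradigm's fixture value.
    """
    cfg = cfg or DltConfig()
    by_region: dict[RegionId, float] = {}
    dp2_weight = 0
    for region in condition.regions:
        if region.dp is not None:
            w = cfg.referent_weight[region.dp.dp_type]
            by_region[region.id] = w
            if region.id is RegionId.DP2:
                dp2_weight = w
        elif region.id is RegionId.VERB:
            pass  # filled after the subject weight is known
        elif region.id is RegionId.SPILL:
            by_region[region.id] = condition.dlt_spill
        else:
            by_region[region.id] = 0
    by_region[RegionId.VERB] = cfg.event_referent_cost + cfg.crossing_cost + dp2_weight
    return RegionCostProfile(label=condition.label, dlt=by_region)
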
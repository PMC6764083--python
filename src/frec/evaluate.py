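"""Model evaluation: correlation with reading times, subject-type
contrasts, and regression of computed grids against the published ones."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import printed
from .derivation import RegionId
from .features import AssignmentTable, CueConfig
from .metrics import DltConfig, dlt_profile, frec_profile
from .paradigms import Paradigm, ReadingTimeTable, english_paradigm, italian_paradigm

__all__ = [
    "CorrelationReport",
    "GridDiff",
    "pearson",
    "correlate_english",
    "subject_type_contrast",
    "verify_against_paper",
]

#: tolerance for comparing rounded log values (printed at 2 decimals)
LOG_TOL = 0.005


@dataclass(frozen=True)
class CorrelationReport:
    """A product-moment correlation between a model predictor and observed
    reading times; ``df`` (n - 2) is carried as metadata only."""

    r: float
    n: int
    pairs: tuple[tuple[str, float, float], ...]

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def r_2dp(self) -> float:
        return round(self.r, 2)


@dataclass(frozen=True)
class GridCell:
    key: str
    expected: float
    computed: float
    match: bool


@dataclass(frozen=True)
class GridDiff:
    """Cell-by-cell comparison of a computed grid against a published one."""

    scope: str
    cells: tuple[GridCell, ...]

    @property
    def mismatches(self) -> int:
        return sum(1 for c in self.cells if not c.match)

    @property
    def ok(self) -> bool:
        return self.mismatches == 0


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard product-moment correlation coefficient.

    Requires equal-length vectors of at least 3 points with non-zero
    variance in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in an input vector")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_english(
    metric: str = "logfrc",
    cue: CueConfig | None = None,
    table: AssignmentTable | None = None,
    paradigm: Paradigm | None = None,
) -> CorrelationReport:
    """Correlate a model predictor with the attached mean reading times of
    the English paradigm.  ``metric`` is ``logfrc`` (verb-region log10 FRC)
    or ``frec`` (verb-region FEC + log10 FRC)."""
    paradigm = paradigm or english_paradigm()
    if paradigm.reading_times is None:
        raise ValueError(f"paradigm {paradigm.name!r} has no attached reading times")
    cue = cue or CueConfig.english()
    table = table or AssignmentTable()
    pairs = []
    for condition in paradigm.conditions:
        profile = frec_profile(condition, cue, table)
        if metric == "logfrc":
            value = profile.log_frc
        elif metric == "frec":
            value = profile.frec_verb
        else:
            raise ValueError(f"unknown metric {metric!r}; use 'logfrc' or 'frec'")
        pairs.append((condition.label, value, float(paradigm.reading_times.mean(condition.label))))
    r = pearson([p[1] for p in pairs], [p[2] for p in pairs])
    return CorrelationReport(r=r, n=len(pairs), pairs=tuple(pairs))


def subject_type_contrast(table: ReadingTimeTable) -> dict[str, int]:
    """Mean reading-time advantages by cleft-subject type on the 3x3
    English table.

    Returns ``{"P2-N2": ..., "N2-D2": ...}`` where each value is how many
    ms faster (positive = faster) the first subject type's conditions are
    read, on average, than the second's, rounded to the nearest integer.
    """
    means = {}
    for subj in ("D2", "N2", "P2"):
        labels = [f"{obj}-{subj}" for obj in ("D1", "N1", "P1")]
        try:
            values = [table.mean(label) for label in labels]
        except KeyError as exc:
            raise ValueError(f"missing condition {exc.args[0]!r}") from None
        means[subj] = sum(values) / len(values)
    return {
        "P2-N2": round(means["N2"] - means["P2"]),
        "N2-D2": round(means["D2"] - means["N2"]),
    }


def _close(expected: float, computed: float, tol: float) -> bool:
    return abs(expected - computed) <= tol


def verify_against_paper(
    scope: str,
    cue: CueConfig | None = None,
    table: AssignmentTable | None = None,
    dlt: DltConfig | None = None,
) -> GridDiff:
    """Recompute one published grid through the full pipeline and diff it
    against the printed values.

    Scopes: ``table14`` (English verb-region log10 FRC column), ``grid16``
    (English 9x6 encoding-cost grid), ``table3`` (Italian per-region
    top-down and memory-load prediction grids).  Logs are compared at
    0.005 (printed precision), integers exactly.
    """
    table = table or AssignmentTable()
    cells: list[GridCell] = []
    if scope == "table14":
        cue = cue or CueConfig.english()
        paradigm = english_paradigm()
        for condition in paradigm.conditions:
            profile = frec_profile(condition, cue, table)
            expected = printed.ENGLISH_LOG_FRC[condition.label]
            computed = profile.log_frc
            cells.append(GridCell(condition.label, expected, computed,
                                  _close(expected, computed, LOG_TOL)))
    elif scope == "grid16":
        cue = cue or CueConfig.english()
        paradigm = english_paradigm()
        region_order = (RegionId.BE, RegionId.DP1, RegionId.C,
                        RegionId.DP2, RegionId.VERB, RegionId.SPILL)
        for condition in paradigm.conditions:
            profile = frec_profile(condition, cue, table)
            expected_row = printed.ENGLISH_FEC_GRID[condition.label]
            for region, expected in zip(region_order, expected_row):
                computed = profile.fec[region]
                cells.append(GridCell(f"{condition.label}:{region.value}",
                                      expected, computed, expected == computed))
    elif scope == "table3":
        cue = cue or CueConfig.italian("H2")
        dlt = dlt or DltConfig.for_assumption("A3")
        paradigm = italian_paradigm()
        for condition in paradigm.conditions:
            profile = frec_profile(condition, cue, table)
            computed_row = {
                "DP1": profile.fec[RegionId.DP1],
                "DP2": profile.fec[RegionId.DP2],
                "VERB": profile.frec_verb,
                "SPILL": profile.fec[RegionId.SPILL],
            }
            for region, expected in printed.ITALIAN_TOPDOWN_GRID[condition.label].items():
                computed = computed_row[region]
                tol = LOG_TOL if region == "VERB" else 0
                cells.append(GridCell(f"top-down:{condition.label}:{region}",
                                      expected, computed, _close(expected, computed, tol)))
            ml = dlt_profile(condition, dlt)
            for region, expected in printed.ITALIAN_MEMLOAD_GRID[condition.label].items():
                computed = ml.dlt[RegionId[region]]
                cells.append(GridCell(f"memory-load:{condition.label}:{region}",
                                      expected, computed, expected == computed))
    else:
        raise ValueError(f"unknown scope {scope!r}; use table14, grid16 or table3")
    return GridDiff(scope=scope, cells=tuple(cells))
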
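"""Estrous-cycle stage calls from smear composition.

The literature defines cytological estrus by percentage criteria that differ
between authors.  Rather than adjudicating, this module exposes the three
most-cited rule sets, selectable by name:

``antonov``
    100% superficial (+ squamous) cells and more than 80% of cells with
    pyknotic or absent nuclei.
``feldman90``
    more than 90% superficial keratinized epithelial cells.
``kustritz``
    100% cornification with more than 50% anuclear squames.

Diestrus onset is called when the superficial + squamous proportion has
dropped by at least 20 percentage points relative to a previous smear and
neutrophil granulocytes are present.  All inequalities are applied exactly
as printed (strict where the source says "more than").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .cell_model import CellClass, ValidationError

__all__ = [
    "Stage",
    "CriterionEval",
    "SmearProfile",
    "StageCall",
    "ESTRUS_RULE_SETS",
    "call_estrus",
    "call_diestrus_onset",
]

_PROPORTION_TOL = 1e-9


class Stage(str, Enum):
    ESTRUS_POSITIVE = "estrus_positive"
    ESTRUS_NEGATIVE = "estrus_negative"
    DIESTRUS_ONSET = "diestrus_onset"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class CriterionEval:
    """One evaluated criterion: the observed value against its threshold."""

    name: str
    observed: float
    threshold: float
    passed: bool


@dataclass(frozen=True)
class SmearProfile:
    """Composition summary of one smear, the input to stage calling.

    ``pyknotic_or_absent_fraction`` counts cells whose nucleus is eroded or
    absent, or demarcated but smaller than the intermediate-cell threshold
    (a pyknosis proxy).  ``anuclear_fraction`` counts cells with no nucleus,
    ``cornified_fraction`` cells with at least two cornification lines.
    """

    proportions: dict[CellClass, float]
    n_cells: int
    pyknotic_or_absent_fraction: float
    anuclear_fraction: float
    cornified_fraction: float
    neutrophils_present: bool = False
    counts: Optional[dict[CellClass, int]] = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells: must be >= 1")
        missing = [c for c in CellClass if c not in self.proportions]
        if missing:
            raise ValidationError(f"proportions: missing classes {missing}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"proportions: must sum to 1, got {total}")
        for name in ("pyknotic_or_absent_fraction", "anuclear_fraction", "cornified_fraction"):
            v = getattr(self, name)
            if not (-_PROPORTION_TOL <= v <= 1 + _PROPORTION_TOL):
                raise ValidationError(f"{name}: must lie in [0, 1], got {v}")

    @property
    def superficial_plus_squamous(self) -> float:
        return self.proportions[CellClass.SUPERFICIAL] + self.proportions[CellClass.SQUAMOUS]


@dataclass(frozen=True)
class StageCall:
    """Structured verdict: the stage, the rule set used and every criterion."""

    stage: Stage
    rule_set: str
    criteria: tuple[CriterionEval, ...]

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValidationError("criteria: a stage call must evaluate at least one criterion")


def _antonov(profile: SmearProfile) -> tuple[CriterionEval, ...]:
    ss = profile.superficial_plus_squamous
    return (
        CriterionEval(
            "superficial_plus_squamous_is_100pct", ss, 1.0, ss >= 1.0 - _PROPORTION_TOL
        ),
        CriterionEval(
            "pyknotic_or_absent_over_80pct",
            profile.pyknotic_or_absent_fraction,
            0.80,
            profile.pyknotic_or_absent_fraction > 0.80,
        ),
    )


def _feldman90(profile: SmearProfile) -> tuple[CriterionEval, ...]:
    ss = profile.superficial_plus_squamous
    return (
        CriterionEval("superficial_keratinized_over_90pct", ss, 0.90, ss > 0.90),
    )


def _kustritz(profile: SmearProfile) -> tuple[CriterionEval, ...]:
    return (
        CriterionEval(
            "cornification_is_100pct",
            profile.cornified_fraction,
            1.0,
            profile.cornified_fraction >= 1.0 - _PROPORTION_TOL,
        ),
        CriterionEval(
            "anuclear_squames_over_50pct",
            profile.anuclear_fraction,
            0.50,
            profile.anuclear_fraction > 0.50,
        ),
    )


ESTRUS_RULE_SETS = {
    "antonov": _antonov,
    "feldman90": _feldman90,
    "kustritz": _kustritz,
}


def call_estrus(profile: SmearProfile, rule_set: str = "kustritz") -> StageCall:
    """Call cytological estrus under one of the literature rule sets.

    Returns ESTRUS_POSITIVE iff every criterion of the selected rule set
    holds, ESTRUS_NEGATIVE otherwise; the call lists each criterion with its
    observed value.
    """
    try:
        rule = ESTRUS_RULE_SETS[rule_set]
    except KeyError:
        raise ValidationError(
            f"rule_set: unknown rule set {rule_set!r}; "
            f"valid options: {sorted(ESTRUS_RULE_SETS)}"
        ) from None
    criteria = rule(profile)
    stage = Stage.ESTRUS_POSITIVE if all(c.passed for c in criteria) else Stage.ESTRUS_NEGATIVE
    return StageCall(stage=stage, rule_set=rule_set, criteria=criteria)


def call_diestrus_onset(
    current: SmearProfile,
    previous: SmearProfile,
    relative: bool = False,
) -> StageCall:
    """Call the onset of diestrus from two consecutive smears.

    The default reading of "decreased by at least 20%" is an absolute drop of
    20 percentage points in the superficial + squamous proportion; set
    ``relative=True`` for a 20% relative decrease instead.  Both the drop and
    the presence of neutrophils are required.
    """
    prev_ss = previous.superficial_plus_squamous
    cur_ss = current.superficial_plus_squamous
    if relative:
        drop = (prev_ss - cur_ss) / prev_ss if prev_ss > 0 else 0.0
        drop_name = "superficial_plus_squamous_relative_drop_20pct"
    else:
        drop = prev_ss - cur_ss
        drop_name = "superficial_plus_squamous_drop_20_points"
    criteria = (
        CriterionEval(drop_name, drop, 0.20, drop >= 0.20),
        CriterionEval(
            "neutrophils_present",
            1.0 if current.neutrophils_present else 0.0,
            1.0,
            current.neutrophils_present,
        ),
    )
    stage = Stage.DIESTRUS_ONSET if all(c.passed for c in criteria) else Stage.INDETERMINATE
    return StageCall(stage=stage, rule_set="relative" if relative else "absolute", criteria=criteria)
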
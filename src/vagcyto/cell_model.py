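"""Domain types and the flowchart classifier for exfoliated canine vaginal cells.

The classifier walks a fixed decision tree over three morphometric features:

1. cell diameter (µm) — cells not exceeding 20.0 µm are parabasal;
2. grade of cornification, operationalized as the count of cornification
   lines — fewer than two lines means "none or slight" cornification;
3. for non-cornified cells, the nuclear area (µm²) — 79.5 µm² or larger
   means intermediate; for cornified (or small-nucleus) cells, nucleus
   visibility and demarcation separate superficial from squamous cells.

Basal cells are deliberately not an output class: they form the lowest
epithelial layer and are not normally exfoliated into a swab sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "NucleusState",
    "CellClass",
    "Step",
    "CellRecord",
    "ClassifierConfig",
    "DecisionTrace",
    "ValidationError",
    "classify_cell",
    "classify_smear",
    "diameter_to_area",
    "area_to_diameter",
]


class ValidationError(ValueError):
    """Raised when a record or configuration violates its invariants."""


class NucleusState(str, Enum):
    """Qualitative state of a cell nucleus as seen on a stained smear."""

    ABSENT = "absent"
    ERODED = "eroded"
    DEMARCATED = "demarcated"


class CellClass(str, Enum):
    """Epithelial cell classes of the vaginal smear (no basal class)."""

    PARABASAL = "parabasal"
    INTERMEDIATE = "intermediate"
    SUPERFICIAL = "superficial"
    SQUAMOUS = "squamous"


class Step(str, Enum):
    """Decision boxes of the classification flowchart, in traversal order."""

    STEP1 = "step1_diameter"
    STEP2 = "step2_cornification"
    STEP2A = "step2a_nucleus_area"
    STEP3A = "step3a_nucleus_visibility"
    STEP3B = "step3b_nucleus_demarcation"


_STEP_ORDER = {s: i for i, s in enumerate(Step)}


@dataclass(frozen=True)
class CellRecord:
    """One measured cell.

    Parameters
    ----------
    cell_id:
        Free-form identifier, ignored by the classifier.
    diameter_um:
        Cell diameter in µm (maximum caliper by convention); must be > 0.
    cornification_lines:
        Number of cornification lines (angular folds), an integer >= 0.
    nucleus_area_um2:
        Nuclear area in µm²; ``None`` exactly when the nucleus is absent.
    nucleus_state:
        ABSENT, ERODED, or DEMARCATED.
    """

    cell_id: str
    diameter_um: float
    cornification_lines: int
    nucleus_area_um2: Optional[float]
    nucleus_state: NucleusState

    def __post_init__(self) -> None:
        if not (isinstance(self.diameter_um, (int, float)) and math.isfinite(self.diameter_um)):
            raise ValidationError("diameter_um: must be a finite number")
        if self.diameter_um <= 0:
            raise ValidationError(f"diameter_um: must be > 0, got {self.diameter_um}")
        if not isinstance(self.cornification_lines, int) or isinstance(self.cornification_lines, bool):
            raise ValidationError("cornification_lines: must be an integer")
        if self.cornification_lines < 0:
            raise ValidationError(
                f"cornification_lines: must be >= 0, got {self.cornification_lines}"
            )
        state = self.nucleus_state
        if not isinstance(state, NucleusState):
            raise ValidationError(f"nucleus_state: unknown state {state!r}")
        if state is NucleusState.ABSENT:
            if self.nucleus_area_um2 is not None:
                raise ValidationError(
                    "nucleus_area_um2: must be absent when nucleus_state is ABSENT"
                )
        else:
            if self.nucleus_area_um2 is None:
                raise ValidationError(
                    f"nucleus_area_um2: required when nucleus_state is {state.name}"
                )
            if not math.isfinite(self.nucleus_area_um2) or self.nucleus_area_um2 < 0:
                raise ValidationError(
                    f"nucleus_area_um2: must be a finite value >= 0, got {self.nucleus_area_um2}"
                )


@dataclass(frozen=True)
class ClassifierConfig:
    """Quantitative thresholds of the flowchart.

    Defaults are the tutorial's published values: a parabasal cell has a
    maximum diameter of 20 µm; two or more cornification lines mean
    moderate-to-significant cornification; a nucleus of 79.5 µm² or larger
    marks an intermediate cell.
    """

    parabasal_max_diameter_um: float = 20.0
    cornified_min_lines: int = 2
    intermediate_min_nucleus_area_um2: float = 79.5

    def __post_init__(self) -> None:
        if self.parabasal_max_diameter_um <= 0:
            raise ValidationError("parabasal_max_diameter_um: must be > 0")
        if not isinstance(self.cornified_min_lines, int) or self.cornified_min_lines < 1:
            raise ValidationError("cornified_min_lines: must be an integer >= 1")
        if self.intermediate_min_nucleus_area_um2 <= 0:
            raise ValidationError("intermediate_min_nucleus_area_um2: must be > 0")


@dataclass
class DecisionTrace:
    """Audit trail of the flowchart traversal for one cell."""

    steps: list[tuple[Step, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def visit(self, step: Step, outcome: str) -> None:
        if self.steps:
            last = self.steps[-1][0]
            if _STEP_ORDER[step] <= _STEP_ORDER[last]:
                raise ValidationError(f"trace: step {step.name} out of flowchart order")
        elif step is not Step.STEP1:
            raise ValidationError("trace: traversal must start at STEP1")
        self.steps.append((step, outcome))


def classify_cell(
    record: CellRecord, config: ClassifierConfig | None = None
) -> tuple[CellClass, DecisionTrace]:
    """Classify one cell by walking the flowchart.

    Returns the class together with a :class:`DecisionTrace` listing every
    decision box visited and its outcome.

    Notes
    -----
    A cell of 20.0 µm exactly is parabasal: only cells whose diameter
    *exceeds* 20.0 µm proceed to the cornification step.  A small cell that
    nevertheless shows cornification lines is still classified parabasal but
    the trace carries a warning, because validation measurements found no
    such cell among 200 sub-20 µm cells.  A large, non-cornified cell with
    no nucleus at all cannot be evaluated at the nuclear-area step and is
    routed directly to nucleus visibility, yielding squamous.
    """
    if config is None:
        config = ClassifierConfig()
    trace = DecisionTrace()

    # Step 1: diameter
    if record.diameter_um <= config.parabasal_max_diameter_um:
        trace.visit(Step.STEP1, f"diameter {record.diameter_um:g} µm <= "
                                f"{config.parabasal_max_diameter_um:g} µm")
        if record.cornification_lines >= 1:
            trace.warnings.append(
                "cell at or below the parabasal maximum diameter shows "
                f"{record.cornification_lines} cornification line(s); "
                "validation measurements found no such cell"
            )
        if record.nucleus_state is not NucleusState.DEMARCATED:
            trace.warnings.append(
                "cell at or below the parabasal maximum diameter has a "
                f"{record.nucleus_state.value} nucleus; validation measurements "
                "found no such cell"
            )
        return CellClass.PARABASAL, trace
    trace.visit(Step.STEP1, f"diameter {record.diameter_um:g} µm exceeds "
                            f"{config.parabasal_max_diameter_um:g} µm")

    # Step 2: grade of cornification
    cornified = record.cornification_lines >= config.cornified_min_lines
    if not cornified:
        trace.visit(Step.STEP2, f"{record.cornification_lines} line(s): none or slight")
        # Step 2.a: size of the nuclear area (evaluable only if a nucleus exists)
        if record.nucleus_area_um2 is not None:
            if record.nucleus_area_um2 >= config.intermediate_min_nucleus_area_um2:
                trace.visit(
                    Step.STEP2A,
                    f"nucleus area {record.nucleus_area_um2:g} µm² >= "
                    f"{config.intermediate_min_nucleus_area_um2:g} µm²",
                )
                return CellClass.INTERMEDIATE, trace
            trace.visit(
                Step.STEP2A,
                f"nucleus area {record.nucleus_area_um2:g} µm² < "
                f"{config.intermediate_min_nucleus_area_um2:g} µm²",
            )
        else:
            trace.visit(Step.STEP2A, "no nucleus: area not evaluable, excluded "
                                     "from intermediate")
    else:
        trace.visit(Step.STEP2, f"{record.cornification_lines} line(s): moderate "
                                "to significant")

    # Step 3.a: visibility of the nucleus
    if record.nucleus_state is NucleusState.ABSENT:
        trace.visit(Step.STEP3A, "no visible nucleus")
        return CellClass.SQUAMOUS, trace
    trace.visit(Step.STEP3A, "nucleus identifiable")

    # Step 3.b: grade of nuclear degeneration
    if record.nucleus_state is NucleusState.DEMARCATED:
        trace.visit(Step.STEP3B, "nucleus definable and demarcated")
        return CellClass.SUPERFICIAL, trace
    trace.visit(Step.STEP3B, "nucleus eroded, only just visible")
    return CellClass.SQUAMOUS, trace


def classify_smear(
    records: list[CellRecord],
    config: ClassifierConfig | None = None,
    neutrophils_present: bool = False,
):
    """Classify every cell of a smear and aggregate into a SmearProfile.

    Besides the per-class proportions, the profile carries the fractions the
    cycle-staging rules consume: cells with pyknotic-or-absent nuclei (state
    ERODED/ABSENT, or a demarcated nucleus smaller than the intermediate
    threshold), anuclear cells, and cornified cells.  Neutrophil presence is
    not derivable from epithelial-cell records and is passed through.
    """
    from .staging import SmearProfile  # local import: staging depends on this module

    if not records:
        raise ValidationError("records: smear must contain at least one cell")
    if config is None:
        config = ClassifierConfig()

    counts = {c: 0 for c in CellClass}
    pyk_or_absent = 0
    anuclear = 0
    cornified = 0
    for rec in records:
        cls, _ = classify_cell(rec, config)
        counts[cls] += 1
        if rec.nucleus_state in (NucleusState.ABSENT, NucleusState.ERODED):
            pyk_or_absent += 1
        elif (
            rec.nucleus_area_um2 is not None
            and rec.nucleus_area_um2 < config.intermediate_min_nucleus_area_um2
        ):
            # pyknosis proxy: demarcated but small (sub-intermediate) nucleus
            pyk_or_absent += 1
        if rec.nucleus_state is NucleusState.ABSENT:
            anuclear += 1
        if rec.cornification_lines >= config.cornified_min_lines:
            cornified += 1

    n = len(records)
    return SmearProfile(
        proportions={c: counts[c] / n for c in CellClass},
        n_cells=n,
        pyknotic_or_absent_fraction=pyk_or_absent / n,
        anuclear_fraction=anuclear / n,
        cornified_fraction=cornified / n,
        neutrophils_present=neutrophils_present,
        counts={c: counts[c] for c in CellClass},
    )


def diameter_to_area(diameter_um: float) -> float:
    """Area (µm²) of a circle with the given diameter (µm).

    Converts nuclear diameters to areas; e.g. the classical 7–11 µm
    intermediate-nucleus diameter range corresponds to about 38.5–95.0 µm².
    """
    if diameter_um < 0:
        raise ValidationError(f"diameter_um: must be >= 0, got {diameter_um}")
    return math.pi * (diameter_um / 2.0) ** 2


def area_to_diameter(area_um2: float) -> float:
    """Equivalent-circle diameter (µm) of the given area (µm²)."""
    if area_um2 < 0:
        raise ValidationError(f"area_um2: must be >= 0, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)
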
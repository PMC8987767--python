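"""Data-driven threshold derivation for the classifier.

Two procedures back the tutorial's quantitative thresholds:

* the nuclear-area threshold separating intermediate from superficial cells
  is the 95th percentile of nucleus areas measured on cornified cells with a
  demarcated nucleus (the published measurement of 200 such nuclei gave a
  mean of 57.7 µm², SD 13.8 µm², and a 95th percentile just under 79.5 µm²);
* the 20 µm parabasal maximum is validated by checking that cells below it
  show neither cornification nor an altered nucleus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cell_model import CellRecord, NucleusState, ValidationError

__all__ = [
    "CalibrationReport",
    "ParabasalValidation",
    "percentile_threshold",
    "validate_parabasal_rule",
    "superficial_nucleus_areas",
]


@dataclass(frozen=True)
class CalibrationReport:
    """Summary of a percentile-threshold calibration run."""

    sample_size: int
    mean_area: float
    sd_area: float
    percentile_q: float
    threshold: float


@dataclass(frozen=True)
class ParabasalValidation:
    """Outcome of checking the parabasal size rule on measured cells.

    ``evaluable`` is False when no cell lies below the diameter cut-off; in
    that case counts are zero and ``rule_holds`` is None.
    """

    max_diameter_um: float
    n_evaluable: int
    n_violations: int
    violation_fraction: float
    evaluable: bool
    rule_holds: bool | None


def percentile_threshold(areas: Sequence[float], q: float = 95.0) -> CalibrationReport:
    """Derive a nuclear-area threshold as the q-th percentile of a sample.

    Uses linear interpolation between closest ranks (the "type 7"
    convention).  The report also carries the sample mean and SD (n-1
    denominator) for comparison against published summary statistics.
    """
    arr = np.asarray(list(areas), dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("areas: need at least two values")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("areas: all values must be finite")
    if np.any(arr < 0):
        raise ValidationError("areas: all values must be >= 0")
    if not (0.0 < q < 100.0):
        raise ValidationError(f"q: percentile must lie in (0, 100), got {q}")
    threshold = float(np.percentile(arr, q, method="linear"))
    return CalibrationReport(
        sample_size=int(arr.size),
        mean_area=float(arr.mean()),
        sd_area=float(arr.std(ddof=1)),
        percentile_q=float(q),
        threshold=threshold,
    )


def validate_parabasal_rule(
    records: Sequence[CellRecord], max_diameter: float = 20.0
) -> ParabasalValidation:
    """Check that cells below the parabasal diameter cut-off show neither
    cornification nor an altered (eroded/absent) nucleus.

    A record violates the rule if its diameter is below ``max_diameter`` and
    it has at least one cornification line or a nucleus state other than
    DEMARCATED.  The rule holds iff the violation fraction is exactly zero.
    """
    if not records:
        raise ValidationError("records: need at least one cell")
    if max_diameter <= 0:
        raise ValidationError("max_diameter: must be > 0")
    small = [r for r in records if r.diameter_um < max_diameter]
    if not small:
        return ParabasalValidation(
            max_diameter_um=max_diameter,
            n_evaluable=0,
            n_violations=0,
            violation_fraction=math.nan,
            evaluable=False,
            rule_holds=None,
        )
    violations = sum(
        1
        for r in small
        if r.cornification_lines >= 1 or r.nucleus_state is not NucleusState.DEMARCATED
    )
    frac = violations / len(small)
    return ParabasalValidation(
        max_diameter_um=max_diameter,
        n_evaluable=len(small),
        n_violations=violations,
        violation_fraction=frac,
        evaluable=True,
        rule_holds=violations == 0,
    )


def superficial_nucleus_areas(
    records: Sequence[CellRecord], min_lines: int = 2
) -> np.ndarray:
    """Extract the nucleus areas entering calibration: cells with at least
    ``min_lines`` cornification lines and a demarcated nucleus."""
    areas = [
        r.nucleus_area_um2
        for r in records
        if r.cornification_lines >= min_lines
        and r.nucleus_state is NucleusState.DEMARCATED
        and r.nucleus_area_um2 is not None
    ]
    return np.asarray(areas, dtype=np.float64)
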
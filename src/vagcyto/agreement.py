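"""Fleiss' kappa inter-rater agreement.

Chance-corrected agreement for a fixed number of raters ``n`` assigning each
of ``N`` subjects to one of ``k`` categories.  With ``n_ij`` the number of
raters assigning subject *i* to category *j*:

    P_i   = 1/(n(n-1)) * sum_j n_ij (n_ij - 1)      per-subject agreement
    P-bar = mean_i P_i                               observed agreement
    p_j   = sum_i n_ij / (N n)                       category proportions
    Pe    = sum_j p_j^2                              chance agreement
    kappa = (P-bar - Pe) / (1 - Pe)

Interpretation bands follow the convention used with this statistic in the
veterinary cytology literature: below 0.40 poor, above 0.75 good, exactly
1.0 perfect, moderate in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cell_model import ValidationError

__all__ = [
    "RatingMatrix",
    "AgreementResult",
    "AgreementBand",
    "UndefinedKappaError",
    "ratings_to_matrix",
    "fleiss_kappa",
    "interpret_kappa",
]


class AgreementBand(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    PERFECT = "perfect"


class UndefinedKappaError(ValidationError):
    """All ratings fall in a single category, so chance agreement is 1 and
    kappa is undefined.  The observed mean agreement is still attached."""

    def __init__(self, mean_agreement: float):
        super().__init__(
            "kappa undefined: every rating is in one category (expected agreement = 1); "
            f"observed mean agreement = {mean_agreement:g}"
        )
        self.mean_agreement = mean_agreement


@dataclass(frozen=True)
class RatingMatrix:
    """N subjects x k categories count matrix with a constant number of
    raters per subject."""

    counts: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts: must be a 2-D subjects x categories matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts: entries must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts: entries must be non-negative")
        N, k = counts.shape
        if N < 1:
            raise ValidationError("counts: need at least one subject")
        if k < 2:
            raise ValidationError("counts: need at least two categories")
        if len(self.categories) != k:
            raise ValidationError(
                f"categories: {len(self.categories)} names for {k} columns"
            )
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            bad = np.flatnonzero(row_sums != row_sums[0]).tolist()
            raise ValidationError(
                f"counts: rows must all sum to the same number of raters; "
                f"offending subject rows: {bad}"
            )
        if row_sums[0] < 2:
            raise ValidationError("counts: need at least two raters per subject")
        object.__setattr__(self, "counts", counts)

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())


@dataclass(frozen=True)
class AgreementResult:
    """Kappa with every intermediate quantity of the computation."""

    per_subject_agreement: np.ndarray
    mean_agreement: float
    expected_agreement: float
    category_proportions: np.ndarray
    kappa: float
    band: AgreementBand
    categories: tuple[str, ...]


def ratings_to_matrix(
    long_table: pd.DataFrame | Iterable[tuple],
    categories: Optional[Sequence[str]] = None,
) -> RatingMatrix:
    """Build a RatingMatrix from long-format (subject, rater, category) rows.

    Every subject must be rated by the same number of distinct raters and no
    (subject, rater) pair may appear twice.  Category column order is the
    order of first appearance unless an explicit ``categories`` list is
    given (which may include categories never used).
    """
    if isinstance(long_table, pd.DataFrame):
        df = long_table.copy()
        expected = ["subject_id", "rater_id", "category"]
        if not set(expected).issubset(df.columns):
            if df.shape[1] == 3:
                df.columns = expected
            else:
                raise ValidationError(
                    f"long table: need columns {expected}, got {list(df.columns)}"
                )
        df = df[expected]
    else:
        rows = list(long_table)
        if not rows:
            raise ValidationError("long table: no ratings")
        df = pd.DataFrame(rows, columns=["subject_id", "rater_id", "category"])
    if df.empty:
        raise ValidationError("long table: no ratings")

    dup = df.duplicated(subset=["subject_id", "rater_id"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "rater_id"]].values.tolist()
        raise ValidationError(f"long table: duplicate (subject, rater) pairs: {pairs}")

    per_subject = df.groupby("subject_id", sort=False)["rater_id"].nunique()
    if per_subject.nunique() > 1:
        counts = per_subject.to_dict()
        raise ValidationError(
            f"long table: unequal raters per subject: {counts}"
        )

    observed = list(dict.fromkeys(df["category"]))
    if categories is None:
        cats = observed
    else:
        cats = list(categories)
        unknown = [c for c in observed if c not in cats]
        if unknown:
            raise ValidationError(
                f"long table: categories {unknown} not in the supplied category list"
            )
    cat_index = {c: j for j, c in enumerate(cats)}

    subjects = list(dict.fromkeys(df["subject_id"]))
    sub_index = {s: i for i, s in enumerate(subjects)}
    counts = np.zeros((len(subjects), len(cats)), dtype=np.int64)
    for s, c in zip(df["subject_id"], df["category"]):
        counts[sub_index[s], cat_index[c]] += 1
    return RatingMatrix(counts=counts, categories=tuple(str(c) for c in cats))


def fleiss_kappa(matrix: RatingMatrix) -> AgreementResult:
    """Compute Fleiss' kappa and all intermediate quantities.

    Raises :class:`UndefinedKappaError` when every rating falls in a single
    category (expected agreement is 1, the denominator vanishes).
    """
    counts = matrix.counts.astype(np.float64)
    N, _k = counts.shape
    n = matrix.n_raters

    p_i = (counts * (counts - 1)).sum(axis=1) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (N * n)
    p_e = float((p_j**2).sum())

    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(p_bar)
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return AgreementResult(
        per_subject_agreement=p_i,
        mean_agreement=p_bar,
        expected_agreement=p_e,
        category_proportions=p_j,
        kappa=float(kappa),
        band=interpret_kappa(kappa),
        categories=matrix.categories,
    )


def interpret_kappa(kappa: float) -> AgreementBand:
    """Band a kappa value: <0.40 poor, 0.40–0.75 moderate, >0.75 good
    (below 1), exactly 1 perfect.  Negative values band as poor."""
    if kappa > 1.0 + 1e-12:
        raise ValidationError(f"kappa: must be <= 1, got {kappa}")
    if kappa >= 1.0:
        return AgreementBand.PERFECT
    if kappa < 0.40:
        return AgreementBand.POOR
    if kappa <= 0.75:
        return AgreementBand.MODERATE
    return AgreementBand.GOOD
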
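"""Densitometry-based classification of RT-PCR validation assays.

For each assayed exon, the relative amount of the alternative product
(as a percentage of all products in the lane) is compared between two
timepoints, giving a linear fold change.  Calls:

* ``minus``     — fold < 2, or the Day-10 change exceeds the Day-7 change
* ``plus``      — fold between 2 and 10 (inclusive at both ends)
* ``plusplus``  — fold > 10

The package ships ``validation_folds.tsv``, the published densitometry
folds of a 30-assay validation panel, for reproducing the panel's
validation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .datamodel import RtPcrRow, UndefinedMetricError


@dataclass(frozen=True)
class ValidationCall:
    probeset_id: str
    fold_d7_vs_d0: float
    fold_d10_vs_d0: Optional[float]
    call: str  # "minus" | "plus" | "plusplus"


def relative_fold(pct_ref: float, pct_cmp: float) -> float:
    """Fold change of a product's relative amount between timepoints."""
    if pct_ref <= 0:
        raise UndefinedMetricError(
            f"reference percentage must be positive, got {pct_ref}"
        )
    if pct_cmp < 0:
        raise UndefinedMetricError(
            f"comparison percentage must be nonnegative, got {pct_cmp}"
        )
    return pct_cmp / pct_ref


def fold_from_row(row: RtPcrRow) -> float:
    """Fold of the alternative product in the row's reported direction."""
    cmp_tp, ref_tp = row.direction.split("/")
    return relative_fold(
        row.percent_by_product[ref_tp][row.alt_product],
        row.percent_by_product[cmp_tp][row.alt_product],
    )


def classify_validation(
    fold_d7: float, fold_d10: Optional[float] = None
) -> str:
    """Classify one assay from its Day-7 (and optional Day-10) fold.

    Folds of exactly 2 or exactly 10 are 'plus' (the boundary is not
    assigned by the strict published inequalities; including it in the
    middle class keeps the class partition total).
    """
    if not math.isfinite(fold_d7) or fold_d7 < 0:
        raise ValueError(f"invalid fold: {fold_d7}")
    if fold_d7 < 2.0:
        return "minus"
    if fold_d10 is not None and fold_d10 > fold_d7:
        return "minus"
    if fold_d7 > 10.0:
        return "plusplus"
    return "plus"


def classify_assays(table: pd.DataFrame) -> list[ValidationCall]:
    """Classify a table with columns probeset_id, fold_d7[, fold_d10]."""
    calls = []
    has_d10 = "fold_d10" in table.columns
    for row in table.itertuples(index=False):
        fold_d10 = None
        if has_d10 and not pd.isna(getattr(row, "fold_d10")):
            fold_d10 = float(getattr(row, "fold_d10"))
        fold_d7 = float(row.fold_d7)
        calls.append(
            ValidationCall(
                probeset_id=str(row.probeset_id),
                fold_d7_vs_d0=fold_d7,
                fold_d10_vs_d0=fold_d10,
                call=classify_validation(fold_d7, fold_d10),
            )
        )
    return calls


def validation_rate(calls: Iterable[ValidationCall]) -> int:
    """Percentage of assays called plus or plusplus, rounded half-up."""
    calls = list(calls)
    if not calls:
        raise ValueError("validation_rate needs at least one call")
    n_changed = sum(c.call in ("plus", "plusplus") for c in calls)
    return int(math.floor(100.0 * n_changed / len(calls) + 0.5))


def call_counts(calls: Iterable[ValidationCall]) -> dict[str, int]:
    counts = {"minus": 0, "plus": 0, "plusplus": 0}
    for c in calls:
        counts[c.call] += 1
    return counts


def load_validation_folds() -> pd.DataFrame:
    """Load the packaged 30-assay published densitometry fold table."""
    with resources.files("dasx.data").joinpath("validation_folds.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
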
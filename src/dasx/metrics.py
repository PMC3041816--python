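"""Splicing-index computation.

The normalized intensity (NI) of a probeset at a timepoint is the ratio
of its intensity to its gene's intensity, computed per replicate and then
averaged over replicates.  Dividing by the gene signal removes gene-level
expression change, so the splicing index

    SI = log2( NI_comparison / NI_reference )

isolates exon-usage change.  The A-value is the mean log2 probeset
intensity over the Day 0 and Day 7 replicates (the x-axis of an MA-style
SI-A plot); together they separate weakly-expressed probesets from
genuinely switched exons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    REPLICATES,
    TIMEPOINTS,
    IntensityPanel,
    ProbesetAnnotation,
    UndefinedMetricError,
)


@dataclass(frozen=True)
class SpliceScores:
    probeset_id: str
    gene_id: str
    ni_mean: dict  # timepoint -> mean NI over replicates (None if undefined)
    si_d7: float
    si_d10: Optional[float]  # None when NI at d10 is zero/undefined
    a_value: float

    @property
    def abs_si_d7(self) -> float:
        return abs(self.si_d7)

    @property
    def abs_si_d10(self) -> Optional[float]:
        return None if self.si_d10 is None else abs(self.si_d10)


def normalized_intensity(
    panel: IntensityPanel,
    annotation: ProbesetAnnotation,
    probeset_id: str,
    timepoint: str,
) -> float:
    """Mean over replicates of (probeset intensity / gene intensity).

    The per-replicate ratio is formed first and then averaged, so unequal
    gene intensities across replicates weight the replicates equally.
    """
    gene_id = annotation.gene_of(probeset_id)
    ps = panel.probeset_values(probeset_id, timepoint).to_numpy(float)
    gn = panel.gene_values(gene_id, timepoint).to_numpy(float)
    if (gn <= 0).any():
        raise UndefinedMetricError(
            f"NI undefined: gene {gene_id} has nonpositive intensity at "
            f"{timepoint}"
        )
    return float(np.mean(ps / gn))


def splicing_index(
    panel: IntensityPanel,
    annotation: ProbesetAnnotation,
    probeset_id: str,
    comparison: str = "d7",
    reference: str = "d0",
) -> float:
    """log2 ratio of mean NI between two timepoints."""
    ni_ref = normalized_intensity(panel, annotation, probeset_id, reference)
    ni_cmp = normalized_intensity(panel, annotation, probeset_id, comparison)
    if ni_ref <= 0 or ni_cmp <= 0:
        raise UndefinedMetricError(
            f"SI undefined for {probeset_id}: NI is zero at "
            f"{reference if ni_ref <= 0 else comparison}"
        )
    return math.log2(ni_cmp / ni_ref)


def fold_from_si(si: float) -> float:
    """Linear fold change equivalent of a splicing index (2**si)."""
    if not math.isfinite(si):
        raise UndefinedMetricError("SI must be finite")
    return 2.0 ** si


def a_value(panel: IntensityPanel, probeset_id: str) -> float:
    """Mean log2 probeset intensity over the d0 and d7 replicates."""
    vals = np.concatenate(
        [
            panel.probeset_values(probeset_id, tp).to_numpy(float)
            for tp in ("d0", "d7")
        ]
    )
    if (vals <= 0).any():
        raise UndefinedMetricError(
            f"A-value undefined for {probeset_id}: nonpositive intensity"
        )
    return float(np.mean(np.log2(vals)))


def score_all(
    panel: IntensityPanel, annotation: ProbesetAnnotation
) -> tuple[dict[str, SpliceScores], list[tuple[str, str]]]:
    """Score every annotated probeset; failures are itemized, not raised.

    Returns (scores keyed by probeset_id, list of (probeset_id, reason)).
    A probeset is scorable when NI is defined and positive at d0 and d7
    and its d0/d7 intensities are positive (for the A-value); si_d10 is
    None when the d10 NI is zero or its gene intensity vanishes there.
    """
    scores: dict[str, SpliceScores] = {}
    failures: list[tuple[str, str]] = []
    # vectorized NI per replicate: probeset row / matching gene row
    ps = panel.probeset_intensity
    genes = [annotation.gene_of(p) for p in ps.index]
    gn = panel.gene_intensity.reindex(genes)
    gn.index = ps.index
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ps.to_numpy(float) / gn.to_numpy(float)
    ratio_df = pd.DataFrame(ratio, index=ps.index, columns=ps.columns)
    ni = {
        tp: ratio_df[[f"{tp}_{r}" for r in REPLICATES]].mean(axis=1)
        for tp in TIMEPOINTS
    }
    gene_ok = {
        tp: (gn[[f"{tp}_{r}" for r in REPLICATES]] > 0).all(axis=1)
        for tp in TIMEPOINTS
    }
    a_cols = [f"{tp}_{r}" for tp in ("d0", "d7") for r in REPLICATES]
    a_ok = (ps[a_cols] > 0).all(axis=1)
    a_vals = np.log2(ps[a_cols].where(ps[a_cols] > 0)).mean(axis=1)

    for pid in ps.index:
        if not (gene_ok["d0"][pid] and gene_ok["d7"][pid]):
            failures.append((pid, "gene intensity nonpositive at d0 or d7"))
            continue
        ni0, ni7 = float(ni["d0"][pid]), float(ni["d7"][pid])
        if ni0 <= 0 or ni7 <= 0:
            failures.append((pid, "NI zero at d0 or d7"))
            continue
        if not a_ok[pid]:
            failures.append((pid, "nonpositive probeset intensity at d0/d7"))
            continue
        si_d7 = math.log2(ni7 / ni0)
        ni10: Optional[float]
        if gene_ok["d10"][pid]:
            ni10 = float(ni["d10"][pid])
        else:
            ni10 = None
        si_d10 = (
            math.log2(ni10 / ni0) if ni10 is not None and ni10 > 0 else None
        )
        scores[pid] = SpliceScores(
            probeset_id=pid,
            gene_id=annotation.gene_of(pid),
            ni_mean={
                "d0": ni0,
                "d7": ni7,
                "d10": ni10 if ni10 is not None and ni10 > 0 else None,
            },
            si_d7=si_d7,
            si_d10=si_d10,
            a_value=float(a_vals[pid]),
        )
    return scores, failures


def si_a_table(scores: dict[str, SpliceScores]) -> pd.DataFrame:
    """Two-column (si_d7, a_value) table for an SI-A scatter plot."""
    return pd.DataFrame(
        {
            "si_d7": [s.si_d7 for s in scores.values()],
            "a_value": [s.a_value for s in scores.values()],
        },
        index=list(scores.keys()),
    )
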
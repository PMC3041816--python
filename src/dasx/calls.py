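"""Detection calls and gene-level expression classification.

A probeset is *detected* at a timepoint when its detection-above-
background (DABG) p-value is at or below alpha in both biological
replicates.  A gene is *expressed* at a timepoint when at least half of
its probesets are detected there.  Expressed genes are classified into
expression-trajectory groups over the Day 0 -> 7 -> 10 course:

* DEX-up: level rises 2- to 10-fold from d0 to d7 and falls from d7 to d10
* DEX-down: level falls 2- to 10-fold from d0 to d7 and rises from d7 to d10

Both fold bounds are inclusive; the d7-vs-d10 reversal is strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    TIMEPOINTS,
    DataConsistencyError,
    DasxError,
    IntensityPanel,
    ProbesetAnnotation,
)


@dataclass(frozen=True)
class GeneExpressionProfile:
    gene_id: str
    expressed_at: dict  # timepoint -> bool
    mean_level: dict  # timepoint -> mean gene intensity over replicates
    dex_class: str  # "up" | "down" | "none"


def probeset_detected(
    panel: IntensityPanel,
    probeset_id: str,
    timepoint: str,
    alpha: float = 0.05,
) -> bool:
    """True iff DABG p <= alpha in both replicates at the timepoint."""
    p = panel.dabg_values(probeset_id, timepoint).to_numpy(float)
    if np.isnan(p).any():
        raise DasxError(
            f"missing DABG replicate for {probeset_id} at {timepoint}"
        )
    return bool((p <= alpha).all())


def gene_expressed(
    panel: IntensityPanel,
    annotation: ProbesetAnnotation,
    gene_id: str,
    timepoint: str,
    alpha: float = 0.05,
    fraction: float = 0.5,
) -> bool:
    """True iff >= *fraction* of the gene's probesets are detected.

    The denominator is all annotated probesets of the gene.
    """
    try:
        records = annotation.by_gene[gene_id]
    except KeyError:
        raise DataConsistencyError(
            f"gene {gene_id!r} not in annotation"
        ) from None
    n_detected = sum(
        probeset_detected(panel, r.probeset_id, timepoint, alpha)
        for r in records
    )
    return n_detected / len(records) >= fraction


def classify_dex(d0: float, d7: float, d10: float) -> str:
    """Classify a gene's mean-level trajectory as 'up', 'down' or 'none'.

    Ratio-based: classify_dex(c*d0, c*d7, c*d10) is identical for c > 0.
    """
    for name, v in (("d0", d0), ("d7", d7), ("d10", d10)):
        if v <= 0:
            raise ValueError(f"nonpositive gene level at {name}: {v}")
    if 2.0 <= d7 / d0 <= 10.0 and d10 < d7:
        return "up"
    if 2.0 <= d0 / d7 <= 10.0 and d10 > d7:
        return "down"
    return "none"


def gene_expression_profiles(
    panel: IntensityPanel,
    annotation: ProbesetAnnotation,
    alpha: float = 0.05,
    fraction: float = 0.5,
) -> dict[str, GeneExpressionProfile]:
    """Expression/DEX profile per annotated gene.

    DEX classification is only attempted for genes expressed on d0 or d7
    (the analysis gate); all other genes are 'none'.
    """
    profiles = {}
    for gene_id in annotation.gene_ids:
        expressed = {
            tp: gene_expressed(panel, annotation, gene_id, tp, alpha, fraction)
            for tp in TIMEPOINTS
        }
        levels = {
            tp: float(panel.gene_values(gene_id, tp).mean())
            for tp in TIMEPOINTS
        }
        if expressed["d0"] or expressed["d7"]:
            dex = classify_dex(levels["d0"], levels["d7"], levels["d10"])
        else:
            dex = "none"
        profiles[gene_id] = GeneExpressionProfile(
            gene_id=gene_id,
            expressed_at=expressed,
            mean_level=levels,
            dex_class=dex,
        )
    return profiles
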
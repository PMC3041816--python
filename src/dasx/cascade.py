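"""The nine-stage extraction cascade.

Stages, applied in order to the full annotated probeset set:

1. remove each gene's first and last probesets (by genomic start)
2. remove probesets with annotated target sequence >= 500 nt (UTR-like)
3. remove probesets flagged for cross-hybridization
4. keep probesets of genes expressed on both Day 0 and Day 7
5. keep probesets detected (DABG) on Day 0 or Day 7
6. keep probesets with |SI_d7| >= 1.35 (2.55-fold exon-usage change)
7. remove probesets whose detectable neighbor probesets all changed
   (|SI_d7| >= 0.667): a genuine alternative exon should border at
   least one constitutive one
8. keep probesets classified alternative against the transcript models
9. keep probesets whose change recedes by Day 10 (|SI_d7| > |SI_d10|)
   or reverses sign past the 1.35 threshold

Every stage records an audit row (surviving probeset and gene counts)
and every removal is itemized with its stage and reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from .calls import gene_expressed, probeset_detected
from .classify import ASCall, classify_probeset_splicing
from .datamodel import (
    ConfigError,
    DataConsistencyError,
    GeneModelSet,
    IntensityPanel,
    PipelineError,
    ProbesetAnnotation,
)
from .metrics import SpliceScores, score_all

logger = logging.getLogger(__name__)

STAGE_DESCRIPTIONS = {
    0: "all annotated probesets",
    1: "remove first/last probeset of each gene",
    2: "remove probesets with target sequence >= 500 nt",
    3: "remove cross-hybridizing probesets",
    4: "keep genes expressed on both d0 and d7",
    5: "keep probesets detected on d0 or d7 (DABG)",
    6: "keep |SI_d7| >= threshold",
    7: "remove probesets whose detectable neighbors all changed",
    8: "keep probesets predicted alternative from transcript models",
    9: "keep probesets receding or reversing by d10",
}


@dataclass(frozen=True)
class CascadeConfig:
    si_threshold: float = 1.35
    neighbor_threshold: float = 0.667
    dabg_alpha: float = 0.05
    max_seq_length: int = 500  # exclusive: kept iff seq_length < this
    expressed_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "si_threshold",
            "neighbor_threshold",
            "dabg_alpha",
            "max_seq_length",
            "expressed_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class AuditRow:
    stage: int
    description: str
    n_probesets: int
    n_genes: int


@dataclass
class CascadeAudit:
    rows: list[AuditRow] = field(default_factory=list)

    def record(self, stage: int, survivors, annotation: ProbesetAnnotation):
        genes = {annotation.by_id[p].gene_id for p in survivors}
        self.rows.append(
            AuditRow(
                stage=stage,
                description=STAGE_DESCRIPTIONS[stage],
                n_probesets=len(survivors),
                n_genes=len(genes),
            )
        )


@dataclass(frozen=True)
class Candidate:
    """One surviving probeset with its scores and event call."""

    probeset_id: str
    gene_id: str
    chrom: str
    start: int
    si_d7: float
    si_d10: Optional[float]
    a_value: float
    as_types: frozenset[str]
    das_direction: str  # "up" (si_d7 >= +thr) or "down" (si_d7 <= -thr)


def _ordered(ids, annotation: ProbesetAnnotation) -> list[str]:
    return sorted(
        ids,
        key=lambda p: (
            annotation.by_id[p].gene_id,
            annotation.by_id[p].start,
            p,
        ),
    )


def f1_remove_terminal(
    annotation: ProbesetAnnotation, survivors=None
) -> set[str]:
    """Drop all probesets sharing each gene's min or max start.

    Terminal probesets often probe UTR or predicted exons outside the
    gene body.  A gene with <= 2 distinct start positions loses all of
    its probesets.
    """
    pool = set(annotation.by_id) if survivors is None else set(survivors)
    kept: set[str] = set()
    for gene_id, records in annotation.by_gene.items():
        # extremes are a property of the gene's full annotation, so the
        # filter is idempotent on its own output
        starts = [r.start for r in records]
        lo, hi = min(starts), max(starts)
        kept.update(
            r.probeset_id
            for r in records
            if r.probeset_id in pool and r.start not in (lo, hi)
        )
    return kept


def f2_remove_long(
    annotation: ProbesetAnnotation, survivors=None, max_seq_length: int = 500
) -> set[str]:
    """Keep probesets with target sequence length strictly below the cap."""
    pool = set(annotation.by_id) if survivors is None else set(survivors)
    return {
        p for p in pool if annotation.by_id[p].seq_length < max_seq_length
    }


def f3_remove_xhyb(annotation: ProbesetAnnotation, survivors=None) -> set[str]:
    """Keep probesets without the cross-hybridization flag."""
    pool = set(annotation.by_id) if survivors is None else set(survivors)
    return {p for p in pool if not annotation.by_id[p].xhyb}


def f4_keep_genes_expressed_both(
    survivors,
    panel: IntensityPanel,
    annotation: ProbesetAnnotation,
    config: CascadeConfig = CascadeConfig(),
) -> set[str]:
    """Keep probesets whose gene is expressed on both d0 and d7.

    The expressed test uses all annotated probesets of the gene as the
    denominator, not just cascade survivors.
    """
    genes = {annotation.by_id[p].gene_id for p in survivors}
    ok = {
        g
        for g in genes
        if gene_expressed(
            panel, annotation, g, "d0", config.dabg_alpha, config.expressed_fraction
        )
        and gene_expressed(
            panel, annotation, g, "d7", config.dabg_alpha, config.expressed_fraction
        )
    }
    return {p for p in survivors if annotation.by_id[p].gene_id in ok}


def f5_keep_detected(
    survivors,
    panel: IntensityPanel,
    config: CascadeConfig = CascadeConfig(),
) -> set[str]:
    """Keep probesets detected (both replicates) at d0 or d7."""
    return {
        p
        for p in survivors
        if probeset_detected(panel, p, "d0", config.dabg_alpha)
        or probeset_detected(panel, p, "d7", config.dabg_alpha)
    }


def f6_si_threshold(
    survivors,
    scores: dict[str, SpliceScores],
    config: CascadeConfig = CascadeConfig(),
) -> set[str]:
    """Keep probesets with |SI_d7| at or above the threshold."""
    kept = set()
    for p in survivors:
        if p not in scores:
            raise PipelineError(
                f"SI undefined for survivor {p} at stage 6 (should have "
                "been removed by the detection filters)"
            )
        if abs(scores[p].si_d7) >= config.si_threshold:
            kept.add(p)
    return kept


def f7_neighbor_rule(
    survivors,
    scores: dict[str, SpliceScores],
    panel: IntensityPanel,
    annotation: ProbesetAnnotation,
    config: CascadeConfig = CascadeConfig(),
    neighbor_pool=None,
) -> set[str]:
    """Remove probesets all of whose detectable neighbors also changed.

    For each candidate the nearest detectable (DABG at d0 or d7),
    non-cross-hybridizing neighbor probeset on each genomic side within
    the same gene is located among probesets surviving the annotation
    filters (stages 1-3).  A neighbor *changed* iff its |SI_d7| >=
    neighbor_threshold.  The candidate is removed iff both located
    neighbors changed (or its only neighbor changed); with no detectable
    neighbor it is kept.
    """
    if neighbor_pool is None:
        pool = f3_remove_xhyb(
            annotation, f2_remove_long(annotation, f1_remove_terminal(annotation))
        )
    else:
        pool = set(neighbor_pool)

    def detectable(p: str) -> bool:
        return (
            probeset_detected(panel, p, "d0", config.dabg_alpha)
            or probeset_detected(panel, p, "d7", config.dabg_alpha)
        ) and p in scores

    kept = set()
    for p in survivors:
        rec = annotation.by_id[p]
        gene_recs = annotation.by_gene[rec.gene_id]
        candidates = [
            r for r in gene_recs if r.probeset_id in pool and r.probeset_id != p
        ]
        upstream = [r for r in candidates if r.start < rec.start]
        downstream = [r for r in candidates if r.start > rec.start]
        neighbors = []
        for side in (reversed(upstream), iter(downstream)):
            for r in side:
                if detectable(r.probeset_id):
                    neighbors.append(r.probeset_id)
                    break
        changed = [
            abs(scores[n].si_d7) >= config.neighbor_threshold for n in neighbors
        ]
        if neighbors and all(changed):
            continue  # removed: no constitutive border remains
        kept.add(p)
    return kept


def f8_as_prediction(
    survivors,
    annotation: ProbesetAnnotation,
    gene_models: GeneModelSet,
) -> tuple[set[str], dict[str, ASCall], list[tuple[str, str]]]:
    """Keep probesets the transcript models call alternative.

    Returns (survivors, ASCall per survivor, itemized removals).
    """
    kept: set[str] = set()
    calls: dict[str, ASCall] = {}
    removed: list[tuple[str, str]] = []
    for p in survivors:
        rec = annotation.by_id[p]
        if rec.gene_id not in gene_models:
            removed.append((p, "no transcript models for gene"))
            logger.warning(
                "probeset %s: gene %s has no transcript models", p, rec.gene_id
            )
            continue
        call = classify_probeset_splicing(
            rec, gene_models.transcripts(rec.gene_id)
        )
        if call.is_alternative:
            kept.add(p)
            calls[p] = call
        else:
            removed.append((p, "constitutive against transcript models"))
    return kept, calls, removed


def f9_direction_rule(
    survivors,
    scores: dict[str, SpliceScores],
    si_threshold: float = 1.35,
) -> tuple[set[str], list[tuple[str, str]]]:
    """Keep probesets whose d7 change recedes or reverses by d10.

    Keep iff |SI_d7| > |SI_d10|, or the sign reverses beyond the SI
    threshold (SI_d7 < 0 with SI_d10 >= +thr, or SI_d7 > 0 with
    SI_d10 <= -thr).  Probesets with undefined SI_d10 are removed with
    an itemized reason.
    """
    kept: set[str] = set()
    removed: list[tuple[str, str]] = []
    for p in survivors:
        s = scores[p]
        if s.si_d10 is None:
            removed.append((p, "SI_d10 undefined"))
            continue
        if (
            abs(s.si_d7) > abs(s.si_d10)
            or (s.si_d7 < 0 and s.si_d10 >= si_threshold)
            or (s.si_d7 > 0 and s.si_d10 <= -si_threshold)
        ):
            kept.add(p)
        else:
            removed.append((p, "change on d10 not smaller than d7"))
    return kept, removed


def run_cascade(
    annotation: ProbesetAnnotation,
    panel: IntensityPanel,
    gene_models: GeneModelSet,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[Candidate], CascadeAudit, list[tuple[str, int, str]]]:
    """Apply all nine stages; return candidates, audit and failures.

    The audit has one row per stage plus the initial census; failures
    itemize every removal with (probeset_id, stage, reason).  Candidates
    are ordered by (gene_id, genomic start).
    """
    ps_index = set(panel.probeset_intensity.index)
    gene_index = set(panel.gene_intensity.index)
    for rec in annotation:
        if rec.probeset_id not in ps_index:
            raise DataConsistencyError(
                f"probeset {rec.probeset_id!r} missing from intensity panel"
            )
        if rec.gene_id not in gene_index:
            raise DataConsistencyError(
                f"gene {rec.gene_id!r} missing from gene intensity table"
            )

    audit = CascadeAudit()
    failures: list[tuple[str, int, str]] = []
    survivors = set(annotation.by_id)
    audit.record(0, survivors, annotation)

    def note_removals(stage: int, before, after, reason: str):
        for p in sorted(before - after):
            failures.append((p, stage, reason))

    prev = survivors
    survivors = f1_remove_terminal(annotation, survivors)
    note_removals(1, prev, survivors, "first/last probeset of gene")
    audit.record(1, survivors, annotation)

    prev = survivors
    survivors = f2_remove_long(annotation, survivors, config.max_seq_length)
    note_removals(2, prev, survivors, "target sequence too long")
    audit.record(2, survivors, annotation)

    prev = survivors
    survivors = f3_remove_xhyb(annotation, survivors)
    note_removals(3, prev, survivors, "cross-hybridization flag")
    audit.record(3, survivors, annotation)

    prev = survivors
    survivors = f4_keep_genes_expressed_both(survivors, panel, annotation, config)
    note_removals(4, prev, survivors, "gene not expressed on both d0 and d7")
    audit.record(4, survivors, annotation)

    prev = survivors
    survivors = f5_keep_detected(survivors, panel, config)
    note_removals(5, prev, survivors, "not detected on d0 or d7")
    audit.record(5, survivors, annotation)

    scores, score_failures = score_all(panel, annotation)
    prev = survivors
    survivors = f6_si_threshold(survivors, scores, config)
    note_removals(6, prev, survivors, "|SI_d7| below threshold")
    audit.record(6, survivors, annotation)

    neighbor_pool = f3_remove_xhyb(
        annotation, f2_remove_long(annotation, f1_remove_terminal(annotation), config.max_seq_length)
    )
    prev = survivors
    survivors = f7_neighbor_rule(
        survivors, scores, panel, annotation, config, neighbor_pool
    )
    note_removals(7, prev, survivors, "all detectable neighbors changed")
    audit.record(7, survivors, annotation)

    survivors, as_calls, removed8 = f8_as_prediction(
        survivors, annotation, gene_models
    )
    for p, reason in removed8:
        failures.append((p, 8, reason))
    audit.record(8, survivors, annotation)

    survivors, removed9 = f9_direction_rule(
        survivors, scores, config.si_threshold
    )
    for p, reason in removed9:
        failures.append((p, 9, reason))
    audit.record(9, survivors, annotation)

    candidates = []
    for p in _ordered(survivors, annotation):
        rec = annotation.by_id[p]
        s = scores[p]
        candidates.append(
            Candidate(
                probeset_id=p,
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                start=rec.start,
                si_d7=s.si_d7,
                si_d10=s.si_d10,
                a_value=s.a_value,
                as_types=as_calls[p].event_types,
                das_direction="up" if s.si_d7 >= config.si_threshold else "down",
            )
        )
    return candidates, audit, failures


def load_published_audit() -> CascadeAudit:
    """The published per-stage survivor counts of the original
    extraction run, as a :class:`CascadeAudit` (for ratio statistics
    such as :func:`fraction_predicted_alternative`)."""
    import json
    from importlib import resources

    text = (
        resources.files("dasx.data")
        .joinpath("published_cascade_counts.json")
        .read_text()
    )
    payload = json.loads(text)
    audit = CascadeAudit()
    for row in payload["stages"]:
        audit.rows.append(
            AuditRow(
                stage=row["stage"],
                description=STAGE_DESCRIPTIONS[row["stage"]],
                n_probesets=row["n_probesets"],
                n_genes=row["n_genes"],
            )
        )
    return audit


def fraction_predicted_alternative(audit: CascadeAudit) -> float:
    """Percentage of SI-selected probesets the annotation-based
    prediction calls alternative: stage-8 survivors over stage-7
    survivors, as a percentage."""
    by_stage = {r.stage: r.n_probesets for r in audit.rows}
    if 7 not in by_stage or 8 not in by_stage or by_stage[7] == 0:
        raise ValueError("audit lacks stage 7/8 counts")
    return 100.0 * by_stage[8] / by_stage[7]
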
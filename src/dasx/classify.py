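"""Annotation-based alternative-exon classification.

Given a probeset interval and all transcript models of its gene, the
probeset is called *alternative* when it is fully contained in an exon of
at least one transcript while being absent from (or only partially
overlapping the exons of) at least one other transcript.  This replaces
sequence-alignment evidence with a user-supplied transcript annotation:
the verdict depends only on the exon-presence matrix over transcripts.

Event types are assigned by comparing the containing exon against each
excluding transcript.  Splice-site-side naming is strand-aware: the
5' splice-site side of an exon is its genomic left edge on '+' and its
genomic right edge on '-'; first/last exons are taken in transcript
orientation.  An overlapping exon that shares neither boundary shifts
both splice sites and is typed {alt_5ss, alt_3ss}; an internal exon with
no overlap in the other transcript is an exon skip even when its flanks
are not interval-identical there (a skip bundled with flank variation).
These two widenings guarantee that every alternative call carries at
least one event type.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datamodel import (
    DataConsistencyError,
    ProbesetRecord,
    TranscriptModel,
)

Interval = tuple[int, int]


@dataclass(frozen=True)
class ASCall:
    probeset_id: str
    is_alternative: bool
    event_types: frozenset[str]
    supporting_transcripts: tuple[str, ...] = ()
    excluding_transcripts: tuple[str, ...] = ()


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def exon_presence(interval: Interval, transcript: TranscriptModel) -> str:
    """'contained' (within one exon), 'partial' (overlap without
    containment) or 'absent'."""
    overlapped = False
    for exon in transcript.exons:
        if _contains(exon, interval):
            return "contained"
        if _overlaps(exon, interval):
            overlapped = True
    return "partial" if overlapped else "absent"


def _five_prime_side(strand: str) -> str:
    return "left" if strand == "+" else "right"


def _containing_exon(interval: Interval, tx: TranscriptModel) -> Interval:
    for exon in tx.exons:
        if _contains(exon, interval):
            return exon
    raise ValueError("interval not contained in any exon")


def _flanks(tx: TranscriptModel, exon: Interval):
    idx = tx.exons.index(exon)
    up = tx.exons[idx - 1] if idx > 0 else None
    down = tx.exons[idx + 1] if idx + 1 < len(tx.exons) else None
    return up, down


def _skipped_with_shared_flanks(
    exon: Interval, host: TranscriptModel, other: TranscriptModel
) -> bool:
    """Strict exon-skip test: *exon* of *host* overlaps no exon of
    *other* and every existing flank is interval-identical in *other*."""
    if any(_overlaps(exon, f) for f in other.exons):
        return False
    up, down = _flanks(host, exon)
    flanks = [f for f in (up, down) if f is not None]
    if not flanks:
        return False
    return all(f in other.exons for f in flanks)


def _pair_events(
    containing_tx: TranscriptModel,
    exon: Interval,
    other: TranscriptModel,
) -> set[str]:
    """Event types implied by *exon* (of containing_tx) vs *other*."""
    strand = containing_tx.strand
    five_side = _five_prime_side(strand)
    events: set[str] = set()

    overlapping = [f for f in other.exons if _overlaps(f, exon)]
    for f in overlapping:
        shared_left = f[0] == exon[0]
        shared_right = f[1] == exon[1]
        if shared_left and shared_right:
            continue
        if shared_left != shared_right:
            differing = "right" if shared_left else "left"
            events.add("alt_5ss" if differing == five_side else "alt_3ss")
        else:  # overlap with both boundaries shifted
            events.update(("alt_5ss", "alt_3ss"))

    # retained intron: exon spans an intron of *other* whose flanking
    # exons both lie within the exon's span
    exs = other.exons
    for i in range(len(exs) - 1):
        if _contains(exon, exs[i]) and _contains(exon, exs[i + 1]):
            events.add("retained_intron")

    if not overlapping:
        if exon == containing_tx.first_exon() and not _overlaps(
            other.first_exon(), exon
        ):
            events.add("alt_promoter")
        if exon == containing_tx.last_exon() and not _overlaps(
            other.last_exon(), exon
        ):
            events.add("alt_terminator")
        up, down = _flanks(containing_tx, exon)
        if up is not None and down is not None:
            # internal skipped exon; strict when flanks are identical,
            # still a skip when the flanks themselves vary
            events.add("exon_skip")
            if _skipped_with_shared_flanks(exon, containing_tx, other):
                for f in other.exons:
                    if not _overlaps(f, exon) and _skipped_with_shared_flanks(
                        f, other, containing_tx
                    ):
                        events.add("mutually_exclusive")
                        break
    return events


def classify_probeset_splicing(
    probeset: ProbesetRecord, transcripts: Sequence[TranscriptModel]
) -> ASCall:
    """Decide whether a probeset interval is alternative for its gene."""
    if not transcripts:
        raise DataConsistencyError(
            f"no transcripts supplied for probeset {probeset.probeset_id}"
        )
    for tx in transcripts:
        if tx.gene_id != probeset.gene_id:
            raise DataConsistencyError(
                f"transcript {tx.transcript_id} belongs to {tx.gene_id}, "
                f"not {probeset.gene_id}"
            )
    interval = probeset.interval
    presence = {tx.transcript_id: exon_presence(interval, tx) for tx in transcripts}
    containing = [tx for tx in transcripts if presence[tx.transcript_id] == "contained"]
    excluding = [tx for tx in transcripts if presence[tx.transcript_id] != "contained"]

    if not containing or not excluding:
        return ASCall(
            probeset_id=probeset.probeset_id,
            is_alternative=False,
            event_types=frozenset(),
            supporting_transcripts=tuple(t.transcript_id for t in containing),
            excluding_transcripts=tuple(t.transcript_id for t in excluding),
        )

    events: set[str] = set()
    for tc in containing:
        exon = _containing_exon(interval, tc)
        for te in excluding:
            events |= _pair_events(tc, exon, te)
    return ASCall(
        probeset_id=probeset.probeset_id,
        is_alternative=True,
        event_types=frozenset(events),
        supporting_transcripts=tuple(t.transcript_id for t in containing),
        excluding_transcripts=tuple(t.transcript_id for t in excluding),
    )


def summarize_as_types(calls: Iterable[ASCall]) -> dict[str, float]:
    """Percentage of each event type among alternative calls.

    A call with k event types contributes 1/k to each of them, so the
    percentages always sum to 100 over a nonempty input.
    """
    weights: Counter = Counter()
    n_alt = 0
    for call in calls:
        if not call.is_alternative:
            continue
        n_alt += 1
        k = len(call.event_types)
        for ev in call.event_types:
            weights[ev] += 1.0 / k
    if n_alt == 0:
        return {}
    return {ev: 100.0 * w / n_alt for ev, w in sorted(weights.items())}
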
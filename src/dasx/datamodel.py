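"""Domain types shared by the whole pipeline.

Conventions
-----------
* Genomic intervals are 0-based, half-open internally.  All text formats
  (annotation tables, GTF) use 1-based inclusive coordinates; the readers
  and writers in :mod:`dasx.io` convert at the boundary.
* The intensity panel covers three timepoints (``d0``, ``d7``, ``d10``,
  i.e. Day 0 / Day 7 / Day 10 of differentiation) with two biological
  replicates (``r1``, ``r2``) each.
* A probeset's ``seq_length`` is the length of the probeset target
  sequence as annotated on the array, NOT the genomic span: long target
  sequences flag probable UTR probesets and are filtered on that column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

TIMEPOINTS: tuple[str, ...] = ("d0", "d7", "d10")
REPLICATES: tuple[str, ...] = ("r1", "r2")
PANEL_COLUMNS: tuple[str, ...] = tuple(
    f"{t}_{r}" for t in TIMEPOINTS for r in REPLICATES
)

#: Controlled vocabulary of alternative-splicing event types.
AS_EVENT_TYPES: tuple[str, ...] = (
    "exon_skip",
    "alt_5ss",
    "alt_3ss",
    "retained_intron",
    "mutually_exclusive",
    "alt_promoter",
    "alt_terminator",
)


class DasxError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(DasxError):
    """A file does not conform to the expected layout (missing column,
    unparsable token, bad coordinate)."""


class DataConsistencyError(DasxError):
    """Two inputs that must agree (e.g. probeset table vs gene table)
    do not."""


class ModelError(DasxError):
    """A transcript model violates its structural invariants."""


class UndefinedMetricError(DasxError):
    """A score (NI, SI, A) is undefined for the requested probeset."""


class PipelineError(DasxError):
    """An internal contract of the filter cascade was violated."""


class ConfigError(DasxError):
    """An invalid simulation or cascade configuration."""


@dataclass(frozen=True)
class ProbesetRecord:
    """Static annotation of one probeset (~ one exon probed on the array)."""

    probeset_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based
    stop: int  # half-open
    strand: str
    seq_length: int
    xhyb: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ModelError(
                f"probeset {self.probeset_id}: invalid interval "
                f"[{self.start}, {self.stop})"
            )
        if self.seq_length <= 0:
            raise ModelError(
                f"probeset {self.probeset_id}: seq_length must be positive"
            )
        if self.strand not in ("+", "-"):
            raise ModelError(
                f"probeset {self.probeset_id}: strand must be '+' or '-'"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.stop)


class ProbesetAnnotation:
    """Indexed collection of :class:`ProbesetRecord`.

    Enforces uniqueness of probeset ids and exposes the two lookups the
    cascade needs: by probeset id, and per gene ordered by genomic start.
    """

    def __init__(self, records: Iterable[ProbesetRecord]):
        self.records: list[ProbesetRecord] = list(records)
        self.by_id: dict[str, ProbesetRecord] = {}
        for rec in self.records:
            if rec.probeset_id in self.by_id:
                raise DataConsistencyError(
                    f"duplicate probeset_id {rec.probeset_id!r}"
                )
            self.by_id[rec.probeset_id] = rec
        self.by_gene: dict[str, list[ProbesetRecord]] = {}
        for rec in self.records:
            self.by_gene.setdefault(rec.gene_id, []).append(rec)
        for recs in self.by_gene.values():
            recs.sort(key=lambda r: (r.start, r.probeset_id))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def gene_of(self, probeset_id: str) -> str:
        try:
            return self.by_id[probeset_id].gene_id
        except KeyError:
            raise DataConsistencyError(
                f"probeset {probeset_id!r} not in annotation"
            ) from None

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.by_gene)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered list of exon intervals on one strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id}: no exons")
        prev_stop = None
        for start, stop in self.exons:
            if start >= stop:
                raise ModelError(
                    f"transcript {self.transcript_id}: empty/inverted exon "
                    f"[{start}, {stop})"
                )
            if prev_stop is not None and start < prev_stop:
                raise ModelError(
                    f"transcript {self.transcript_id}: exons overlap or are "
                    "unsorted"
                )
            prev_stop = stop

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def first_exon(self) -> tuple[int, int]:
        """5'-most exon in transcript orientation."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def last_exon(self) -> tuple[int, int]:
        """3'-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


class GeneModelSet:
    """Mapping gene_id -> transcripts, with per-gene strand/chrom checks."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        for tx in transcripts:
            self.by_gene.setdefault(tx.gene_id, []).append(tx)
        for gene_id, txs in self.by_gene.items():
            strands = {t.strand for t in txs}
            chroms = {t.chrom for t in txs}
            if len(strands) > 1 or len(chroms) > 1:
                raise ModelError(
                    f"gene {gene_id}: transcripts disagree on strand/chrom"
                )
            txs.sort(key=lambda t: t.transcript_id)

    def __len__(self) -> int:
        return len(self.by_gene)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_gene

    def transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return self.by_gene[gene_id]

    def all_transcripts(self) -> list[TranscriptModel]:
        return [tx for txs in self.by_gene.values() for tx in txs]


@dataclass
class IntensityPanel:
    """Probeset- and gene-level intensity estimates plus detection p-values.

    Each table is indexed by id with one column per (timepoint, replicate)
    pair, named ``d0_r1`` ... ``d10_r2``.
    """

    probeset_intensity: pd.DataFrame
    gene_intensity: pd.DataFrame
    dabg_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (
            ("probeset_intensity", self.probeset_intensity),
            ("gene_intensity", self.gene_intensity),
            ("dabg_p", self.dabg_p),
        ):
            missing = [c for c in PANEL_COLUMNS if c not in df.columns]
            if missing:
                raise DataFormatError(f"{name}: missing columns {missing}")
        if set(self.probeset_intensity.index) != set(self.dabg_p.index):
            raise DataConsistencyError(
                "probeset intensity and DABG tables list different probesets"
            )
        if (self.probeset_intensity[list(PANEL_COLUMNS)] < 0).any().any():
            raise DataFormatError("negative probeset intensity")
        if (self.gene_intensity[list(PANEL_COLUMNS)] <= 0).any().any():
            raise DataFormatError("gene intensities must be strictly positive")
        dab = self.dabg_p[list(PANEL_COLUMNS)]
        if ((dab < 0) | (dab > 1)).any().any():
            raise DataFormatError("DABG p-values must lie in [0, 1]")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.probeset_intensity.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_intensity.index)

    def probeset_values(self, probeset_id: str, timepoint: str) -> pd.Series:
        cols = [f"{timepoint}_{r}" for r in REPLICATES]
        try:
            return self.probeset_intensity.loc[probeset_id, cols]
        except KeyError:
            raise DataConsistencyError(
                f"probeset {probeset_id!r} not in panel"
            ) from None

    def gene_values(self, gene_id: str, timepoint: str) -> pd.Series:
        cols = [f"{timepoint}_{r}" for r in REPLICATES]
        try:
            return self.gene_intensity.loc[gene_id, cols]
        except KeyError:
            raise DataConsistencyError(
                f"gene {gene_id!r} not in panel"
            ) from None

    def dabg_values(self, probeset_id: str, timepoint: str) -> pd.Series:
        cols = [f"{timepoint}_{r}" for r in REPLICATES]
        try:
            return self.dabg_p.loc[probeset_id, cols]
        except KeyError:
            raise DataConsistencyError(
                f"probeset {probeset_id!r} not in DABG table"
            ) from None


@dataclass(frozen=True)
class RtPcrRow:
    """One semiquantitative RT-PCR assay: per-product densitometry
    percentages at each timepoint, plus which product carries the
    alternative exon and which ratio direction is reported."""

    gene: str
    probeset_id: str
    product_lengths: tuple[int, ...]
    percent_by_product: Mapping[str, Mapping[int, float]]
    alt_product: int
    direction: str  # "d7/d0" or "d0/d7"

    def __post_init__(self) -> None:
        if self.alt_product not in self.product_lengths:
            raise DataConsistencyError(
                f"{self.probeset_id}: alt_product {self.alt_product} not "
                "among product_lengths"
            )
        if self.direction not in ("d7/d0", "d0/d7"):
            raise DataFormatError(
                f"{self.probeset_id}: direction must be 'd7/d0' or 'd0/d7'"
            )
        for tp, pcts in self.percent_by_product.items():
            total = sum(pcts.values())
            if abs(total - 100.0) > 0.5:
                raise DataConsistencyError(
                    f"{self.probeset_id}: product percentages at {tp} sum to "
                    f"{total:g}, not 100"
                )
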
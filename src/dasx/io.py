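"""Readers and writers for every external format the pipeline touches.

External coordinates (annotation tables, GTF) are 1-based inclusive;
everything returned by these functions is 0-based half-open, and the
writers convert back, so a read/write round trip is the identity.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd

from .datamodel import (
    PANEL_COLUMNS,
    DataConsistencyError,
    DataFormatError,
    GeneModelSet,
    IntensityPanel,
    ModelError,
    ProbesetAnnotation,
    ProbesetRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_ANNOTATION_COLUMNS = (
    "probeset_id",
    "gene_id",
    "chrom",
    "start",
    "stop",
    "strand",
    "seq_length",
    "xhyb",
)

_TRUE_TOKENS = {"true", "t", "1", "yes"}
_FALSE_TOKENS = {"false", "f", "0", "no"}


def _parse_bool(token: str, row: int) -> bool:
    low = str(token).strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise DataFormatError(
        f"row {row}: cannot parse xhyb token {token!r} as boolean"
    )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_probeset_annotation(path) -> ProbesetAnnotation:
    """Read a probeset annotation table (comma- or tab-delimited).

    File coordinates are 1-based inclusive and are converted to the
    internal 0-based half-open convention.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path.name}: missing annotation column(s) {missing}"
        )
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start1 = int(row.start)
            stop1 = int(row.stop)
            seq_length = int(row.seq_length)
        except ValueError as exc:
            raise DataFormatError(f"row {row_no}: {exc}") from None
        if start1 < 1 or stop1 < start1:
            raise DataFormatError(
                f"row {row_no}: invalid 1-based interval {start1}..{stop1}"
            )
        records.append(
            ProbesetRecord(
                probeset_id=str(row.probeset_id),
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                start=start1 - 1,
                stop=stop1,
                strand=str(row.strand),
                seq_length=seq_length,
                xhyb=_parse_bool(row.xhyb, row_no),
            )
        )
    return ProbesetAnnotation(records)


def write_probeset_annotation(annotation: ProbesetAnnotation, path) -> None:
    """Write an annotation table (tab-delimited, 1-based inclusive)."""
    rows = [
        {
            "probeset_id": r.probeset_id,
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "start": r.start + 1,
            "stop": r.stop,
            "strand": r.strand,
            "seq_length": r.seq_length,
            "xhyb": str(r.xhyb).lower(),
        }
        for r in annotation
    ]
    df = pd.DataFrame(rows, columns=list(_ANNOTATION_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def _read_panel_table(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path.name} ({kind}): missing columns {missing}")
    if df.index.has_duplicates:
        raise DataConsistencyError(f"{path.name} ({kind}): duplicate ids")
    return df[list(PANEL_COLUMNS)].astype(float)


def read_intensity_panel(
    probeset_path,
    gene_path,
    dabg_path,
    annotation: Optional[ProbesetAnnotation] = None,
) -> IntensityPanel:
    """Read the three tab-delimited panel tables.

    When *annotation* is given, every annotated probeset must appear in
    the probeset and DABG tables and its gene in the gene table.
    """
    panel = IntensityPanel(
        probeset_intensity=_read_panel_table(probeset_path, "probeset"),
        gene_intensity=_read_panel_table(gene_path, "gene"),
        dabg_p=_read_panel_table(dabg_path, "dabg"),
    )
    if annotation is not None:
        ps_index = set(panel.probeset_intensity.index)
        gene_index = set(panel.gene_intensity.index)
        for rec in annotation:
            if rec.probeset_id not in ps_index:
                raise DataConsistencyError(
                    f"probeset {rec.probeset_id!r} annotated but absent from "
                    "intensity table"
                )
            if rec.gene_id not in gene_index:
                raise DataConsistencyError(
                    f"gene {rec.gene_id!r} (probeset {rec.probeset_id!r}) "
                    "absent from gene intensity table"
                )
    return panel


def write_intensity_panel(panel: IntensityPanel, outdir) -> dict[str, Path]:
    """Write the three panel tables into *outdir*; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probeset": outdir / "probeset_intensity.tsv",
        "gene": outdir / "gene_intensity.tsv",
        "dabg": outdir / "dabg_p.tsv",
    }
    for key, df in (
        ("probeset", panel.probeset_intensity),
        ("gene", panel.gene_intensity),
        ("dabg", panel.dabg_p),
    ):
        out = df.copy()
        out.index.name = "id"
        out.to_csv(paths[key], sep="\t", float_format="%.6g")
    return paths


def read_transcript_models(path) -> GeneModelSet:
    """Read transcript models from a GTF file (exon features only).

    Transcript features with no exon lines are skipped with a warning;
    overlapping exons within one transcript raise :class:`ModelError`.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # malformed GTF surfaces as a format error
        raise DataFormatError(f"{path.name}: cannot parse GTF ({exc})") from exc

    exons_by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise DataFormatError(
                f"{path.name}: exon feature missing {exc} attribute"
            ) from None
        if feat.start > feat.end:
            raise ModelError(
                f"transcript {tx_id}: exon with start > end "
                f"({feat.start} > {feat.end})"
            )
        entry = exons_by_tx.setdefault(
            tx_id,
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
            },
        )
        entry["exons"].append((feat.start - 1, feat.end))

    for feat in db.features_of_type("transcript"):
        tx_id = feat.attributes.get("transcript_id", [feat.id])[0]
        if tx_id not in exons_by_tx:
            logger.warning(
                "transcript %s has no exon features; skipped", tx_id
            )

    transcripts = []
    for tx_id, entry in exons_by_tx.items():
        exons = tuple(sorted(entry["exons"]))
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=entry["gene_id"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=exons,
            )
        )
    return GeneModelSet(transcripts)


def write_transcript_models(models: GeneModelSet, path) -> None:
    """Write a GeneModelSet as GTF (exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in sorted(
            models.all_transcripts(), key=lambda t: (t.gene_id, t.transcript_id)
        ):
            for start, stop in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; '
                    f'transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            "dasx",
                            "exon",
                            str(start + 1),
                            str(stop),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


CANDIDATE_COLUMNS = (
    "probeset_id",
    "gene_id",
    "chrom",
    "start",
    "si_d7",
    "si_d10",
    "a_value",
    "as_types",
    "das_direction",
)


def write_candidate_table(candidates: Iterable, path) -> None:
    """Write the final candidate list, sorted by gene then genomic start.

    Start coordinates are emitted 1-based inclusive, matching the
    annotation dialect.
    """
    rows = []
    for c in candidates:
        rows.append(
            {
                "probeset_id": c.probeset_id,
                "gene_id": c.gene_id,
                "chrom": c.chrom,
                "start": c.start + 1,
                "si_d7": f"{c.si_d7:.6g}",
                "si_d10": "NA" if c.si_d10 is None else f"{c.si_d10:.6g}",
                "a_value": f"{c.a_value:.6g}",
                "as_types": ",".join(sorted(c.as_types)),
                "das_direction": c.das_direction,
            }
        )
    rows.sort(key=lambda r: (r["gene_id"], r["start"], r["probeset_id"]))
    df = pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_candidate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"candidate table missing columns {missing}")
    return df


def write_audit(audit, path) -> None:
    """Write a cascade audit; ``.json`` suffix selects JSON, else TSV."""
    path = Path(path)
    rows = [
        {
            "stage": r.stage,
            "description": r.description,
            "n_probesets": r.n_probesets,
            "n_genes": r.n_genes,
        }
        for r in audit.rows
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        pd.DataFrame(
            rows, columns=["stage", "description", "n_probesets", "n_genes"]
        ).to_csv(path, sep="\t", index=False)


def write_failures(failures: Iterable, path) -> None:
    """Itemized exclusions: (probeset_id, stage, reason) per row."""
    df = pd.DataFrame(
        [
            {"probeset_id": f[0], "stage": f[1], "reason": f[2]}
            for f in failures
        ],
        columns=["probeset_id", "stage", "reason"],
    )
    df.to_csv(path, sep="\t", index=False)
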
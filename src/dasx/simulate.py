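"""Synthetic exon-array dataset generator with embedded ground truth.

The generator emulates summarized probeset/gene intensity panels over a
three-timepoint (Day 0 / 7 / 10), two-replicate differentiation course:

* gene intensity  = baseline x trajectory(t) x log-normal noise
* probeset intensity = gene intensity x probeset affinity x NI(t)
  x log-normal noise

where NI(t) is the true normalized intensity: 1 at all timepoints for
constitutive probesets, and shifted by ``2**delta_si`` at Day 7 (with a
fraction ``d10_relaxation`` of the log2 effect retained at Day 10) for
probesets on a true differentially-spliced region.  Effects are injected
on NI — the exact quantity the splicing index measures — so the
configured ``delta_si`` is directly comparable to the detection
threshold.

Each differentially-spliced gene carries one alternative transcript
realizing a concrete internal event (cassette exon, retained intron, or
an alternative 5'/3' splice site), so the annotation-based classifier
can rediscover it.  Terminal events are never injected because the
cascade removes each gene's outermost probesets by design.  Detection
p-values follow a two-regime uniform model around ``detect_floor``, and
a configurable fraction of constitutive probesets receive long target
sequences or cross-hybridization flags so the annotation filters have
work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datamodel import (
    PANEL_COLUMNS,
    REPLICATES,
    TIMEPOINTS,
    ConfigError,
    DataConsistencyError,
    GeneModelSet,
    IntensityPanel,
    ProbesetAnnotation,
    ProbesetRecord,
    TranscriptModel,
)

_DAS_EVENTS = ("exon_skip", "retained_intron", "alt_5ss", "alt_3ss")


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 500
    transcripts_per_gene: tuple[int, int] = (1, 2)
    exons_per_transcript: tuple[int, int] = (5, 9)
    probesets_per_exon: tuple[int, int] = (1, 2)
    das_fraction: float = 0.1
    delta_si: float = 2.0
    d10_relaxation: float = 0.3
    dex_up_fraction: float = 0.1
    dex_down_fraction: float = 0.1
    noise_cv: float = 0.1
    detect_floor: float = 50.0
    xhyb_fraction: float = 0.05
    long_probeset_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        for name in (
            "das_fraction",
            "dex_up_fraction",
            "dex_down_fraction",
            "xhyb_fraction",
            "long_probeset_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if (
            self.das_fraction + self.dex_up_fraction + self.dex_down_fraction
            > 1.0 + 1e-12
        ):
            raise ConfigError(
                "das_fraction + dex fractions must not exceed 1 (the groups "
                "are disjoint by design)"
            )
        if self.das_fraction > 0 and self.delta_si == 0:
            raise ConfigError("delta_si must be nonzero when das_fraction > 0")
        if not 0.0 <= self.d10_relaxation < 1.0:
            raise ConfigError("d10_relaxation must be in [0, 1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        for name in (
            "transcripts_per_gene",
            "exons_per_transcript",
            "probesets_per_exon",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must be a (lo, hi) range with lo >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    true_das_probesets: dict[str, str]  # probeset_id -> "+" | "-"
    true_dex_up: set[str]
    true_dex_down: set[str]
    ni_true: pd.DataFrame  # index probeset_id, columns d0/d7/d10
    das_event_by_gene: dict[str, str] = field(default_factory=dict)

    @property
    def probeset_ids(self) -> set[str]:
        return set(self.ni_true.index)


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    precision: float
    fdr: float
    n_true: int
    n_candidates: int
    n_hits: int


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_dataset(
    config: SimConfig,
) -> tuple[ProbesetAnnotation, GeneModelSet, IntensityPanel, SyntheticTruth]:
    """Generate a complete synthetic dataset with known truth.

    The same config (including seed) always yields an identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n_das = int(round(config.das_fraction * config.n_genes))
    n_up = int(round(config.dex_up_fraction * config.n_genes))
    n_down = int(round(config.dex_down_fraction * config.n_genes))
    if n_das > config.n_genes:
        raise ConfigError("more DAS genes requested than genes")

    records: list[ProbesetRecord] = []
    transcripts: list[TranscriptModel] = []
    truth_das: dict[str, str] = {}
    das_event_by_gene: dict[str, str] = {}
    ni_rows: dict[str, tuple[float, float, float]] = {}
    meta: list[dict] = []  # per-probeset generation metadata
    gene_meta: list[dict] = []

    chrom_cursor: dict[str, int] = {}
    ps_counter = 0

    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        chrom = f"chr{gi % 5 + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        is_das = gi < n_das
        is_up = n_das <= gi < n_das + n_up
        is_down = n_das + n_up <= gi < n_das + n_up + n_down

        lo, hi = config.exons_per_transcript
        n_exons = int(rng.integers(lo, hi + 1))
        if is_das:
            n_exons = max(n_exons, 5)
        cursor = chrom_cursor.get(chrom, 1000) + int(rng.integers(5000, 20000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(90, 300))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(200, 801))
        chrom_cursor[chrom] = cursor
        base = tuple(exons)

        das_direction = None
        das_intervals: list[tuple[int, int]] = []
        if is_das:
            event = _DAS_EVENTS[gi % len(_DAS_EVENTS)]
            das_event_by_gene[gene_id] = event
            das_direction = "+" if rng.random() < 0.5 else "-"
            if event == "exon_skip":
                j = int(rng.integers(1, n_exons - 1))
                alt = base[:j] + base[j + 1 :]
                das_intervals.append(base[j])
            elif event == "retained_intron":
                j = int(rng.integers(1, n_exons - 2))
                merged = (base[j][0], base[j + 1][1])
                alt = base[:j] + (merged,) + base[j + 2 :]
                intron = (base[j][1], base[j + 1][0])
                pad = max(5, (intron[1] - intron[0]) // 10)
                das_intervals.append((intron[0] + pad, intron[1] - pad))
            else:  # alternative 5'/3' splice site: extend one boundary
                j = int(rng.integers(1, n_exons - 1))
                ext = 80
                if event == "alt_5ss":
                    moved = (base[j][0] - ext, base[j][1])
                    region = (base[j][0] - ext + 5, base[j][0] - 5)
                else:
                    moved = (base[j][0], base[j][1] + ext)
                    region = (base[j][1] + 5, base[j][1] + ext - 5)
                alt = base[:j] + (moved,) + base[j + 1 :]
                das_intervals.append(region)
            transcripts.append(
                TranscriptModel(f"{gene_id}_t1", gene_id, chrom, strand, base)
            )
            transcripts.append(
                TranscriptModel(f"{gene_id}_t2", gene_id, chrom, strand, alt)
            )
        else:
            tlo, thi = config.transcripts_per_gene
            n_tx = int(rng.integers(tlo, thi + 1))
            for k in range(n_tx):
                transcripts.append(
                    TranscriptModel(
                        f"{gene_id}_t{k + 1}", gene_id, chrom, strand, base
                    )
                )

        # gene-level trajectory and baseline
        baseline = float(rng.lognormal(math.log(500.0), 0.8))
        if is_das or is_up or is_down:
            baseline = max(baseline, 8.0 * config.detect_floor)
        if is_up:
            f7 = float(rng.uniform(3.0, 8.0))
            traj = (1.0, f7, f7 * float(rng.uniform(0.3, 0.8)))
        elif is_down:
            f7 = float(rng.uniform(3.0, 8.0))
            d7 = 1.0 / f7
            traj = (1.0, d7, d7 * float(rng.uniform(1.3, 2.5)))
        else:
            traj = (1.0, 1.0, 1.0)
        gene_meta.append(
            {"gene_id": gene_id, "baseline": baseline, "traj": traj}
        )

        # probesets: tile every exon of the base transcript, then add
        # the differentially-spliced region(s)
        def add_probeset(interval, is_das_ps):
            nonlocal ps_counter
            ps_counter += 1
            pid = f"ps{ps_counter:06d}"
            span = interval[1] - interval[0]
            meta.append(
                {
                    "probeset_id": pid,
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": interval[0],
                    "stop": interval[1],
                    "strand": strand,
                    "span": span,
                    "is_das": is_das_ps,
                }
            )
            return pid

        plo, phi = config.probesets_per_exon
        skip_exon = (
            das_intervals[0]
            if is_das and das_event_by_gene[gene_id] == "exon_skip"
            else None
        )
        for exon in base:
            n_ps = int(rng.integers(plo, phi + 1))
            width = (exon[1] - exon[0]) // n_ps
            exon_is_das = skip_exon is not None and exon == skip_exon
            for k in range(n_ps):
                a = exon[0] + k * width
                b = exon[1] if k == n_ps - 1 else a + width
                pid = add_probeset((a, b), exon_is_das)
                if exon_is_das:
                    truth_das[pid] = das_direction
        if is_das and skip_exon is None:
            for interval in das_intervals:
                pid = add_probeset(interval, True)
                truth_das[pid] = das_direction

    # annotation flags (long target sequence / cross-hybridization) on
    # constitutive probesets only, so the injected truth is recoverable
    n_ps_total = len(meta)
    u_long = rng.random(n_ps_total)
    u_xhyb = rng.random(n_ps_total)
    long_len = rng.integers(500, 1500, size=n_ps_total)
    for i, m in enumerate(meta):
        if not m["is_das"] and u_long[i] < config.long_probeset_fraction:
            m["seq_length"] = int(long_len[i])
        else:
            m["seq_length"] = int(min(m["span"], 499))
        m["xhyb"] = bool(
            not m["is_das"] and u_xhyb[i] < config.xhyb_fraction
        )

    records = [
        ProbesetRecord(
            probeset_id=m["probeset_id"],
            gene_id=m["gene_id"],
            chrom=m["chrom"],
            start=m["start"],
            stop=m["stop"],
            strand=m["strand"],
            seq_length=m["seq_length"],
            xhyb=m["xhyb"],
        )
        for m in meta
    ]
    annotation = ProbesetAnnotation(records)
    gene_models = GeneModelSet(transcripts)

    # intensity panel
    gene_ids = [g["gene_id"] for g in gene_meta]
    ps_ids = [m["probeset_id"] for m in meta]
    gene_mat = np.zeros((len(gene_ids), len(PANEL_COLUMNS)))
    for row, g in enumerate(gene_meta):
        traj_per_col = np.repeat(g["traj"], len(REPLICATES))
        noise = _lognormal_noise(rng, config.noise_cv, len(PANEL_COLUMNS))
        gene_mat[row] = g["baseline"] * traj_per_col * noise
    gene_df = pd.DataFrame(gene_mat, index=gene_ids, columns=list(PANEL_COLUMNS))

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    ps_mat = np.zeros((len(ps_ids), len(PANEL_COLUMNS)))
    affinities = np.exp(rng.normal(0.0, 0.3, size=len(ps_ids)))
    for i, m in enumerate(meta):
        pid = m["probeset_id"]
        if pid in truth_das:
            sgn = 1.0 if truth_das[pid] == "+" else -1.0
            ni = (
                1.0,
                2.0 ** (sgn * config.delta_si),
                2.0 ** (sgn * config.delta_si * config.d10_relaxation),
            )
        else:
            ni = (1.0, 1.0, 1.0)
        ni_rows[pid] = ni
        ni_per_col = np.repeat(ni, len(REPLICATES))
        noise = _lognormal_noise(rng, config.noise_cv, len(PANEL_COLUMNS))
        ps_mat[i] = (
            gene_mat[gene_row[m["gene_id"]]] * affinities[i] * ni_per_col * noise
        )
    ps_df = pd.DataFrame(ps_mat, index=ps_ids, columns=list(PANEL_COLUMNS))

    detected = ps_mat >= config.detect_floor
    p_low = rng.uniform(0.0, 0.01, size=ps_mat.shape)
    p_high = rng.uniform(0.1, 1.0, size=ps_mat.shape)
    dabg = pd.DataFrame(
        np.where(detected, p_low, p_high),
        index=ps_ids,
        columns=list(PANEL_COLUMNS),
    )

    panel = IntensityPanel(
        probeset_intensity=ps_df, gene_intensity=gene_df, dabg_p=dabg
    )
    ni_true = pd.DataFrame(
        [ni_rows[p] for p in ps_ids],
        index=ps_ids,
        columns=list(TIMEPOINTS),
    )
    truth = SyntheticTruth(
        true_das_probesets=truth_das,
        true_dex_up={g["gene_id"] for gi2, g in enumerate(gene_meta) if n_das <= gi2 < n_das + n_up},
        true_dex_down={
            g["gene_id"]
            for gi2, g in enumerate(gene_meta)
            if n_das + n_up <= gi2 < n_das + n_up + n_down
        },
        ni_true=ni_true,
        das_event_by_gene=das_event_by_gene,
    )
    return annotation, gene_models, panel, truth


def evaluate_recovery(
    candidates: Iterable[str], truth: SyntheticTruth
) -> RecoveryMetrics:
    """Sensitivity/precision/FDR of a candidate set against the truth.

    With no candidates the precision is defined as 1 (no false
    discoveries were made); sensitivity is then 0 unless the truth is
    also empty, in which case it is 1.
    """
    cand = set(candidates)
    universe = truth.probeset_ids
    unknown = cand - universe
    if unknown:
        raise DataConsistencyError(
            f"candidate ids not in dataset: {sorted(unknown)[:5]}"
        )
    true_set = set(truth.true_das_probesets)
    hits = cand & true_set
    sensitivity = len(hits) / len(true_set) if true_set else 1.0
    precision = len(hits) / len(cand) if cand else 1.0
    return RecoveryMetrics(
        sensitivity=sensitivity,
        precision=precision,
        fdr=1.0 - precision,
        n_true=len(true_set),
        n_candidates=len(cand),
        n_hits=len(hits),
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the truth table: one row per probeset with DAS status."""
    rows = []
    for pid in truth.ni_true.index:
        rows.append(
            {
                "probeset_id": pid,
                "das": truth.true_das_probesets.get(pid, ""),
                "ni_d0": f"{truth.ni_true.loc[pid, 'd0']:.6g}",
                "ni_d7": f"{truth.ni_true.loc[pid, 'd7']:.6g}",
                "ni_d10": f"{truth.ni_true.loc[pid, 'd10']:.6g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
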
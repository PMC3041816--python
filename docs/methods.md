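# Methods

## Model and assumptions

`dasx` operates entirely on *summarized* data: one intensity per
probeset and per gene for each (timepoint, replicate) cell, plus a
detection-above-background (DABG) p-value per probeset cell. Probe-level
summarization (PLIER-style), array normalization and background
modelling are upstream of this package and out of its scope; the
readers validate but never transform intensities.

The central assumption is that the probeset/gene intensity ratio
(normalized intensity, NI) cancels gene-level expression change, so its
log2 ratio between conditions — the splicing index (SI) — isolates
exon-usage change. This holds when probeset response is approximately
linear in transcript abundance and the gene estimate is dominated by
constitutive exons; a gene whose estimate is itself driven by the
switching exon attenuates the SI, which is one reason the cascade also
demands an unchanged neighboring probeset.

NI is computed per replicate and then averaged (not as a ratio of
averaged intensities): with two replicates this weights the replicates
equally regardless of their gene-level intensity, and it is the order
fixed by defining SI on "averaged NIs".

The A-value is the mean of log2 probeset intensity over the four
Day 0/Day 7 cells (MA-plot convention). Averaging in log space rather
than linear space, and pooling replicates with timepoints, were free
choices; log-space pooling matches how MA plots are normally drawn and
makes the A-value shift additively under per-timepoint rescaling.

No pseudocounts are used anywhere. NI/SI/A that are undefined (zero or
negative inputs) are surfaced as itemized failures; in normal operation
the detection filters remove such probesets before any score is needed,
which is the pipeline's own mechanism for avoiding degenerate values.

## The cascade

Stages and their parameters (all in `CascadeConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `si_threshold` | 1.35 (log2) | minimum |SI_d7|; 2^1.35 ≈ 2.55-fold |
| `neighbor_threshold` | 0.667 (log2) | neighbor counted as "changed" at or above this |
| `dabg_alpha` | 0.05 | detection p-value cutoff, inclusive |
| `max_seq_length` | 500 nt | probesets at or above this are UTR-like, removed |
| `expressed_fraction` | 0.5 | fraction of a gene's probesets detected for "expressed" |

Boundary conventions, chosen once and applied consistently:

- Detection requires p ≤ α in **both** replicates. This is applied
  uniformly — to the gene "expressed" rule and to the per-probeset
  detection of stages 5 and 7 — although the stage-5 rule could also be
  read as per-array; the stricter uniform reading keeps one detection
  primitive throughout.
- Stage 1 removes *all* probesets tying at a gene's extreme start
  coordinates (conservative tie handling), computes extremes on the
  gene's full annotation (making the filter idempotent), and orders by
  genomic start regardless of strand, since array probeset
  identifiers are genome-ordered.
- Stage 2 keeps `seq_length < 500` strictly; the length is the
  annotated probeset target-sequence length, not the genomic span.
- Stage 6 and the DEX fold bounds are inclusive (≥ 1.35; 2–10-fold).
- Stage 7's neighbor search space is the probesets surviving the
  annotation filters (stages 1–3) that are detectable and scorable —
  not just stage-6 survivors, otherwise no unchanged neighbor could
  exist. A candidate with no detectable neighbor is kept (no evidence
  against it). A neighbor at exactly 0.667 counts as changed.
- Stage 9 keeps |SI_d7| > |SI_d10| (strict), or a sign reversal beyond
  the SI threshold (SI_d7 < 0 with SI_d10 ≥ +1.35, or the mirror
  image); probesets whose SI_d10 is undefined are removed with an
  itemized reason.
- DEX trajectories: "decreased from Day 7 to Day 10" is strict; the
  gene mean level is the arithmetic mean of the two replicates; DEX is
  only assigned to genes expressed on Day 0 or Day 7; the denominator
  of "expressed" is all annotated probesets of the gene.

Every stage appends an audit row (surviving probesets and distinct
genes) and every removal is itemized as (probeset, stage, reason), so a
run is fully reconstructible from its outputs.

## Alternative-exon classification

The original evidence base for "is this exon alternative?" was sequence
alignment of probeset targets against transcript/EST databases with
manual curation. This package substitutes a deterministic,
annotation-based rule over a user-supplied GTF — the single largest
substitution in the design, and deliberately so: it is reproducible and
testable, at the cost of only seeing events present in the annotation.

A probeset is **alternative** when its interval is fully contained in
an exon of at least one transcript of its gene and absent from (or only
partially overlapping) the exons of at least one other transcript — a
property of the exon-presence matrix over transcripts. Event types are
then derived by comparing the containing exon with each excluding
transcript: exon skip (no overlap, internal), alternative 5'/3' splice
site (an overlapping exon sharing exactly one boundary; sides are
strand-aware, with the 5' splice-site side being the genomic left edge
on `+`), retained intron (the exon spans a consecutive exon pair of the
other transcript), mutually exclusive (skip holds symmetrically for a
non-overlapping exon pair), and alternative promoter/terminator
(transcript-orientation first/last exons that do not overlap the other
transcript's corresponding terminal exon).

Two widenings keep the verdict and the typing consistent (every
alternative call carries ≥ 1 type): an overlapping exon sharing
*neither* boundary shifts both splice sites and is typed
`{alt_5ss, alt_3ss}`, and an internal exon with no overlap in the other
transcript is an exon skip even when its flanking exons are not
interval-identical there (a skip bundled with flank variation). Under
these rules, mirroring all coordinates *and* flipping strand (the same
biological gene) preserves every call, while mirroring without the
strand flip swaps 5'↔3' and promoter↔terminator — both properties are
tested.

Multi-type probesets are real (validated examples combine skip with
splice-site selection), so `event_types` is a set, and the type summary
uses fractional attribution: a probeset with k types contributes 1/k to
each, keeping the distribution normalized.

## RT-PCR validation classification

Inputs are per-product densitometry percentages (each lane summing to
100%) or pre-computed folds of the alternative product's relative
amount in the assay's reported direction. Calls: `minus` below 2-fold
(or when a supplied Day-10 fold exceeds the Day-7 fold), `plusplus`
above 10-fold, `plus` between. Folds of exactly 2 or 10 fall in the
middle class: the published strict inequalities leave the boundary
unassigned, no published value sits on it, and assigning it inward
keeps the partition total. The validation rate is the percentage of
`plus`/`plusplus` calls rounded half-up, which maps 26/30 to 87. The
packaged `validation_folds.tsv` transcribes the 30 published assay
folds.

## The synthetic-data generator

What it emulates: a three-timepoint, two-replicate panel whose
gene intensities are baseline × trajectory × log-normal noise and whose
probeset intensities are the realized gene intensity × per-probeset
affinity (log-normal, σ=0.3) × true NI × log-normal noise. Effects are
injected on NI, the exact quantity SI thresholds, so `delta_si=2.0` is
directly comparable to the 1.35 cutoff. DABG p-values follow a
two-regime uniform model: U(0, 0.01) when the realized intensity clears
`detect_floor`, U(0.1, 1) otherwise, keeping the 0.05 cutoff
meaningful without modelling background probes.

Defaults (the standard regime): 500 genes, 5–9 exons per transcript,
1–2 probesets per exon, 10% of genes with one true splicing event of
effect 2.0 log2 units at Day 7 with 30% retained at Day 10, 10% DEX-up
and 10% DEX-down genes (disjoint from the spliced set), 10%
multiplicative noise CV, detection floor 50 on a gene-intensity
baseline log-normal around 500, 5% long-target and 5% cross-hybridizing
probesets. Gene baselines in the spliced/DEX groups are floored at
8× the detection floor so that every embedded event occurs in an
expressed gene — a construction guarantee, not a measurement.

Constraints built into the generator, and why:

- Injected events are internal (cassette exon, retained intron,
  alternative 5'/3' splice site, cycled deterministically across
  spliced genes), each realized by a base/alternative transcript pair
  so the model-based filter can find it. Terminal events are never
  injected because stage 1 removes terminal probesets by construction;
  a generator that injected them would measure its own annotation
  artefact, not the detector.
- Long-target and cross-hybridization flags are only assigned to
  constitutive probesets, for the same reason.
- Constitutive genes carry 1–2 identical-structure transcripts, so the
  classifier correctly calls their probesets constitutive.

What it does **not** emulate — and hence what passing tests do not show
about real arrays: probe-level summarization artefacts, spatial or
batch effects, correlated noise between probesets of one gene,
cross-hybridization *signal* (only the flag), partial isoform mixtures
(true NI shifts are pure), annotation errors, and genes whose estimate
is dominated by the switching exon. Recovery numbers on synthetic data
are therefore an internal-consistency measure of the cascade under its
own assumptions, not a field performance estimate.

Determinism: a single seeded generator drives all draws in a fixed
order, so identical configs produce byte-identical output files.

## Problem sizes and numerical choices

The test suite and the acceptance script use 15–500-gene simulations
(a 500-gene dataset is ~5,000 probesets and runs through the full
cascade in a few seconds), 500–600 random gene models for the
classifier oracle, and exact hand-built fixtures for the per-stage
audit. Straight-line oracle checks run at ≤ 20 genes where per-cell
re-evaluation is cheap. Floating-point policy: no tolerance is applied
inside the filters (thresholds compare raw floats); tests compare
scores with relative tolerances ~1e-9 except the no-noise limit, where
SI is only guaranteed zero to one ulp of the intensity-ratio division.

## Known limitations

- The annotation-based alternative call can only rediscover events
  representable in the supplied GTF; novel exons are invisible.
- With two replicates and no variance model, detection and fold rules
  are deliberately threshold-based; there is no error control, and the
  cascade's specificity rests on the SI threshold and the neighbor
  rule rather than on a test statistic.
- A gene whose probesets nearly all change (global isoform switch)
  can fail the neighbor rule by design; complex events spanning many
  adjacent exons are at a disadvantage.
- The published absolute per-stage survivor counts depend on the
  original raw arrays, summarization pipeline and a contemporaneous
  transcript-evidence database; they are shipped as a reference table
  for ratio statistics, not reproduced by computation here.
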
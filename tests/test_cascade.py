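"""The nine-stage filter cascade: per-stage rules, audit, and the
straight-line oracle equivalence."""

import numpy as np
import pytest

from dasx import (
    CascadeConfig,
    GeneModelSet,
    ProbesetAnnotation,
    SimConfig,
    TranscriptModel,
    run_cascade,
    simulate_dataset,
)
from dasx.cascade import (
    f1_remove_terminal,
    f2_remove_long,
    f3_remove_xhyb,
    f5_keep_detected,
    f6_si_threshold,
    f7_neighbor_rule,
    f9_direction_rule,
)
from dasx.metrics import SpliceScores, score_all
from _oracles import straight_line_survivors
from conftest import make_panel, make_record


def score(pid, si_d7, si_d10=0.0, gene="g1"):
    return SpliceScores(
        probeset_id=pid, gene_id=gene,
        ni_mean={"d0": 1.0, "d7": 1.0, "d10": 1.0},
        si_d7=si_d7, si_d10=si_d10, a_value=5.0,
    )


class TestTerminalFilter:
    def test_middle_probeset_survives(self):
        ann = ProbesetAnnotation(
            [make_record(f"ps{i}", "g1", start=s, stop=s + 10)
             for i, s in enumerate([10, 50, 90])]
        )
        assert f1_remove_terminal(ann) == {"ps1"}

    def test_two_probeset_gene_loses_all(self):
        ann = ProbesetAnnotation(
            [make_record("ps1", "g1", start=10, stop=20),
             make_record("ps2", "g1", start=50, stop=60)]
        )
        assert f1_remove_terminal(ann) == set()

    def test_all_start_ties_removed(self):
        ann = ProbesetAnnotation(
            [make_record("a", "g1", start=10, stop=20),
             make_record("b", "g1", start=10, stop=30),
             make_record("c", "g1", start=50, stop=60),
             make_record("d", "g1", start=90, stop=95)]
        )
        # brute-force enumeration: survivors are records whose start is
        # neither the min nor the max of the gene
        starts = [10, 10, 50, 90]
        expected = {
            pid for pid, s in zip("abcd", starts)
            if s != min(starts) and s != max(starts)
        }
        assert f1_remove_terminal(ann) == expected == {"c"}

    def test_idempotent(self):
        ann = ProbesetAnnotation(
            [make_record(f"ps{i}", "g1", start=10 * i + 10, stop=10 * i + 15)
             for i in range(6)]
        )
        once = f1_remove_terminal(ann)
        assert f1_remove_terminal(ann, once) == once


class TestLengthAndXhybFilters:
    @pytest.mark.parametrize("length, kept", [(499, True), (500, False), (501, False)])
    def test_length_boundary(self, length, kept):
        ann = ProbesetAnnotation([make_record("ps1", "g1", seq_length=length)])
        assert (f2_remove_long(ann) == {"ps1"}) is kept

    def test_xhyb_counts(self):
        ann = ProbesetAnnotation(
            [make_record(f"ps{i}", "g1", start=10 * i + 1, stop=10 * i + 5,
                         xhyb=(i < 3))
             for i in range(10)]
        )
        assert len(f3_remove_xhyb(ann)) == 7


class TestDetectionFilters:
    def _panel(self, dabg):
        ps = {p: [100.0] * 6 for p in dabg}
        return make_panel(ps, {"g1": [100.0] * 6}, dabg)

    def test_detected_on_either_day_kept(self):
        panel = self._panel({
            "d0_only": [0.01, 0.01, 0.9, 0.9, 0.9, 0.9],
            "neither": [0.9] * 6,
            "d10_only": [0.9, 0.9, 0.9, 0.9, 0.01, 0.01],
        })
        survivors = f5_keep_detected({"d0_only", "neither", "d10_only"}, panel)
        assert survivors == {"d0_only"}


class TestSIThreshold:
    @pytest.mark.parametrize(
        "si, kept", [(1.35, True), (-1.36, True), (1.34, False)]
    )
    def test_inclusive_boundary(self, si, kept):
        scores = {"ps1": score("ps1", si)}
        assert (f6_si_threshold({"ps1"}, scores) == {"ps1"}) is kept


class TestNeighborRule:
    def _setup(self, neighbor_sis, candidate_si=2.0):
        """Gene with probesets n_left*, candidate, n_right* in start order,
        plus terminal padding so stage-1 never interferes."""
        records = [make_record("pad_l", "g1", start=5, stop=8)]
        scores = {}
        starts = iter(range(100, 100 + 100 * (len(neighbor_sis) + 1), 100))
        n_ids = []
        left = neighbor_sis[: len(neighbor_sis) // 2 + len(neighbor_sis) % 2]
        # candidate goes in the middle
        order = []
        if len(neighbor_sis) == 2:
            order = [("nl", neighbor_sis[0]), ("cand", candidate_si), ("nr", neighbor_sis[1])]
        elif len(neighbor_sis) == 1:
            order = [("cand", candidate_si), ("nr", neighbor_sis[0])]
        else:
            order = [("cand", candidate_si)]
        for pid, si in order:
            s = next(starts)
            records.append(make_record(pid, "g1", start=s, stop=s + 10))
            scores[pid] = score(pid, si)
        records.append(make_record("pad_r", "g1", start=5000, stop=5008))
        ann = ProbesetAnnotation(records)
        panel = make_panel(
            {r.probeset_id: [100.0] * 6 for r in records},
            {"g1": [100.0] * 6},
        )
        scores["pad_l"] = score("pad_l", 0.0)
        scores["pad_r"] = score("pad_r", 0.0)
        return ann, panel, scores

    def test_one_unchanged_neighbor_keeps(self):
        ann, panel, scores = self._setup([0.2, 2.0])
        assert f7_neighbor_rule({"cand"}, scores, panel, ann) == {"cand"}

    def test_both_changed_neighbors_remove(self):
        ann, panel, scores = self._setup([1.0, 2.0])
        assert f7_neighbor_rule({"cand"}, scores, panel, ann) == set()

    def test_boundary_0667_counts_as_changed(self):
        ann, panel, scores = self._setup([0.667, 0.667])
        assert f7_neighbor_rule({"cand"}, scores, panel, ann) == set()

    def test_single_unchanged_neighbor_keeps(self):
        ann, panel, scores = self._setup([0.5])
        survivors = f7_neighbor_rule(
            {"cand"}, scores, panel, ann,
            neighbor_pool={"cand", "nr"},
        )
        assert survivors == {"cand"}

    def test_single_changed_neighbor_removes(self):
        ann, panel, scores = self._setup([0.8])
        survivors = f7_neighbor_rule(
            {"cand"}, scores, panel, ann,
            neighbor_pool={"cand", "nr"},
        )
        assert survivors == set()

    def test_no_detectable_neighbor_keeps(self):
        ann, panel, scores = self._setup([])
        survivors = f7_neighbor_rule(
            {"cand"}, scores, panel, ann, neighbor_pool={"cand"}
        )
        assert survivors == {"cand"}


class TestDirectionRule:
    @pytest.mark.parametrize(
        "si_d7, si_d10, kept",
        [
            (2.0, 1.0, True),    # change recedes
            (1.5, -1.5, True),   # reversal past the threshold
            (-1.5, 1.35, True),  # reversal, other sign, boundary inclusive
            (1.0, 1.2, False),   # change grows
            (1.0, -1.2, False),  # reversal too weak, change not receding
        ],
    )
    def test_rule(self, si_d7, si_d10, kept):
        scores = {"ps1": score("ps1", si_d7, si_d10)}
        survivors, removed = f9_direction_rule({"ps1"}, scores)
        assert (survivors == {"ps1"}) is kept

    def test_undefined_si_d10_removed_with_reason(self):
        scores = {"ps1": score("ps1", 2.0, None)}
        survivors, removed = f9_direction_rule({"ps1"}, scores)
        assert survivors == set()
        assert removed == [("ps1", "SI_d10 undefined")]


def build_hand_fixture():
    """Three genes designed so exactly one probeset survives all stages.

    gA: 7 probesets; a3 is a cassette exon with SI_d7=log2(6), receding
        by d10; aL is long (600 nt), aX cross-hybridizing; a1/a5 terminal.
    gB: b3 changes like a3 but its two neighbors change too (|SI|=1.0),
        so stage 7 removes it.
    gC: its probesets are undetected on d7, so stage 4 removes the gene.
    """
    recs, ps_rows, dabg = [], {}, {}

    def add(pid, gene, start, stop, vals, seq_length=60, xhyb=False, dab=None):
        recs.append(make_record(pid, gene, start=start, stop=stop,
                                seq_length=seq_length, xhyb=xhyb))
        ps_rows[pid] = vals
        dabg[pid] = dab if dab is not None else [0.01] * 6

    flat = [50.0, 50.0, 50.0, 50.0, 50.0, 50.0]
    das = [10.0, 10.0, 60.0, 60.0, 15.0, 15.0]   # SI_d7=log2 6, SI_d10=log2 1.5
    semi = [25.0, 25.0, 50.0, 50.0, 50.0, 50.0]  # SI_d7=1.0 (changed neighbor)

    add("a1", "gA", 100, 150, flat)
    add("a2", "gA", 200, 250, flat)
    add("a3", "gA", 300, 350, das)
    add("a4", "gA", 400, 450, flat)
    add("aL", "gA", 450, 470, flat, seq_length=600)
    add("aX", "gA", 470, 490, flat, xhyb=True)
    add("a5", "gA", 500, 550, flat)

    add("b1", "gB", 1000, 1050, flat)
    add("b2", "gB", 1100, 1150, semi)
    add("b3", "gB", 1200, 1250, das)
    add("b4", "gB", 1300, 1350, semi)
    add("b5", "gB", 1400, 1450, flat)

    undetect_d7 = [0.01, 0.01, 0.9, 0.9, 0.01, 0.01]
    add("c1", "gC", 2000, 2050, flat, dab=undetect_d7)
    add("c2", "gC", 2100, 2150, das, dab=undetect_d7)
    add("c3", "gC", 2200, 2250, flat, dab=undetect_d7)

    annotation = ProbesetAnnotation(recs)
    panel = make_panel(
        ps_rows,
        {"gA": [100.0] * 6, "gB": [100.0] * 6, "gC": [100.0] * 6},
        dabg,
    )
    exonsA = ((100, 150), (200, 250), (300, 350), (400, 450), (500, 550))
    models = GeneModelSet(
        [
            TranscriptModel("tA1", "gA", "chr1", "+", exonsA),
            TranscriptModel("tA2", "gA", "chr1", "+",
                            ((100, 150), (200, 250), (400, 450), (500, 550))),
            TranscriptModel("tB1", "gB", "chr1", "+",
                            tuple((1000 + 100 * i, 1050 + 100 * i) for i in range(5))),
        ]
    )
    return annotation, panel, models


class TestRunCascade:
    def test_hand_fixture_audit_and_survivor(self):
        """Brute-force evaluation of all nine rules on the designed
        fixture: only a3 survives, with these per-stage counts."""
        annotation, panel, models = build_hand_fixture()
        candidates, audit, failures = run_cascade(annotation, panel, models)
        counts = [(r.stage, r.n_probesets, r.n_genes) for r in audit.rows]
        assert counts == [
            (0, 15, 3), (1, 9, 3), (2, 8, 3), (3, 7, 3), (4, 6, 2),
            (5, 6, 2), (6, 2, 2), (7, 1, 1), (8, 1, 1), (9, 1, 1),
        ]
        (cand,) = candidates
        assert cand.probeset_id == "a3"
        assert cand.das_direction == "up"
        assert cand.si_d7 == pytest.approx(np.log2(6))
        assert "exon_skip" in cand.as_types
        assert ("b3", 7, "all detectable neighbors changed") in failures

    def test_empty_annotation(self):
        ann, models, panel, _ = simulate_dataset(SimConfig(n_genes=0))
        candidates, audit, failures = run_cascade(ann, panel, models)
        assert candidates == [] and failures == []
        assert all(r.n_probesets == 0 for r in audit.rows)

    def test_no_effect_no_noise_yields_zero_candidates(self):
        cfg = SimConfig(n_genes=40, das_fraction=0.0, noise_cv=0.0, seed=11)
        ann, models, panel, _ = simulate_dataset(cfg)
        candidates, audit, _ = run_cascade(ann, panel, models)
        assert candidates == []
        by_stage = {r.stage: r.n_probesets for r in audit.rows}
        assert by_stage[6] == 0

    def test_audit_monotone_and_gene_counts_consistent(self):
        cfg = SimConfig(n_genes=60, seed=5)
        ann, models, panel, _ = simulate_dataset(cfg)
        _, audit, _ = run_cascade(ann, panel, models)
        for prev, cur in zip(audit.rows, audit.rows[1:]):
            assert cur.n_probesets <= prev.n_probesets
            assert cur.n_genes <= prev.n_genes

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_straight_line_oracle_equivalence(self, seed):
        """The cascade survivor set equals an independent straight-line
        re-evaluation of the nine predicates on small random datasets."""
        cfg = SimConfig(n_genes=15, seed=seed)
        ann, models, panel, _ = simulate_dataset(cfg)
        candidates, _, _ = run_cascade(ann, panel, models)
        got = {c.probeset_id for c in candidates}
        expected = straight_line_survivors(ann, panel, models, CascadeConfig())
        assert got == expected

    def test_recovery_on_standard_regime(self):
        from dasx import evaluate_recovery

        cfg = SimConfig(n_genes=200, seed=3)
        ann, models, panel, truth = simulate_dataset(cfg)
        candidates, _, _ = run_cascade(ann, panel, models)
        m = evaluate_recovery([c.probeset_id for c in candidates], truth)
        assert m.sensitivity >= 0.85 and m.precision >= 0.8
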
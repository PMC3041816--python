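"""Independent straight-line re-implementations used as test oracles.

These deliberately avoid the package's pipeline machinery: plain loops,
per-cell lookups, and the filtering predicates written out one after
another, so that agreement with the pipeline is a meaningful check.
"""

import math


def brute_presence(interval, transcript):
    """Presence of an interval against a transcript's exons."""
    overlapped = False
    for (a, b) in transcript.exons:
        if a <= interval[0] and interval[1] <= b:
            return "contained"
        if interval[0] < b and a < interval[1]:
            overlapped = True
    return "partial" if overlapped else "absent"


def brute_alternative(record, transcripts):
    """Matrix verdict: contained somewhere AND not contained elsewhere."""
    states = [brute_presence((record.start, record.stop), t) for t in transcripts]
    return ("contained" in states) and any(s != "contained" for s in states)


def straight_line_survivors(annotation, panel, models, cfg):
    """Apply the nine filtering predicates one by one, without the
    cascade driver, scoring cache or audit plumbing."""
    ps = {r.probeset_id: r for r in annotation}
    by_gene = {}
    for r in annotation:
        by_gene.setdefault(r.gene_id, []).append(r)

    def dabg(p, tp, rep):
        return float(panel.dabg_p.loc[p, f"{tp}_{rep}"])

    def detected(p, tp):
        return dabg(p, tp, "r1") <= cfg.dabg_alpha and dabg(p, tp, "r2") <= cfg.dabg_alpha

    def ni(p, tp):
        g = ps[p].gene_id
        total = 0.0
        for rep in ("r1", "r2"):
            num = float(panel.probeset_intensity.loc[p, f"{tp}_{rep}"])
            den = float(panel.gene_intensity.loc[g, f"{tp}_{rep}"])
            total += num / den
        return total / 2.0

    def si(p, tp):
        return math.log2(ni(p, tp) / ni(p, "d0"))

    # stages 1-3: annotation-only predicates
    pool13 = set()
    for g, recs in by_gene.items():
        lo = min(r.start for r in recs)
        hi = max(r.start for r in recs)
        for r in recs:
            if r.start != lo and r.start != hi and r.seq_length < cfg.max_seq_length and not r.xhyb:
                pool13.add(r.probeset_id)
    keep = set(pool13)

    # stage 4: gene expressed on both d0 and d7
    def gene_expressed(g, tp):
        recs = by_gene[g]
        n = sum(1 for r in recs if detected(r.probeset_id, tp))
        return n / len(recs) >= cfg.expressed_fraction

    keep = {
        p for p in keep
        if gene_expressed(ps[p].gene_id, "d0") and gene_expressed(ps[p].gene_id, "d7")
    }

    # stage 5: probeset detected on d0 or d7
    keep = {p for p in keep if detected(p, "d0") or detected(p, "d7")}

    # stage 6: |SI_d7| at or above threshold
    keep = {p for p in keep if abs(si(p, "d7")) >= cfg.si_threshold}

    # stage 7: neighbor rule over the stage 1-3 pool
    def neighbor_usable(p):
        return p in pool13 and (detected(p, "d0") or detected(p, "d7"))

    kept7 = set()
    for p in keep:
        recs = sorted(by_gene[ps[p].gene_id], key=lambda r: (r.start, r.probeset_id))
        lefts = [r.probeset_id for r in recs
                 if r.start < ps[p].start and neighbor_usable(r.probeset_id)]
        rights = [r.probeset_id for r in recs
                  if r.start > ps[p].start and neighbor_usable(r.probeset_id)]
        neighbors = ([lefts[-1]] if lefts else []) + ([rights[0]] if rights else [])
        if neighbors and all(abs(si(n, "d7")) >= cfg.neighbor_threshold for n in neighbors):
            continue
        kept7.add(p)
    keep = kept7

    # stage 8: alternative against the transcript models
    kept8 = set()
    for p in keep:
        g = ps[p].gene_id
        if g in models and brute_alternative(ps[p], models.transcripts(g)):
            kept8.add(p)
    keep = kept8

    # stage 9: receding or reversing by d10
    kept9 = set()
    for p in keep:
        s7 = si(p, "d7")
        s10 = si(p, "d10")
        if abs(s7) > abs(s10) or (s7 < 0 and s10 >= cfg.si_threshold) or (s7 > 0 and s10 <= -cfg.si_threshold):
            kept9.add(p)
    return kept9
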
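"""Naive per-base / per-pair reference implementations.

These deliberately use the slowest, most transparent formulation possible
(explicit base sets and double loops) so the production interval engine
can be checked against them exactly.
"""

from repeat_regprof.formats_io import as_interval


def base_set(iv):
    iv = as_interval(iv)
    return {(iv.chrom, b) for b in range(iv.start, iv.end)}


def oracle_intersect_fraction(queries, targets, f):
    pairs = set()
    for qi, q in enumerate(queries):
        qb = base_set(q)
        for ti, t in enumerate(targets):
            shared = len(qb & base_set(t))
            if shared >= f * len(qb):
                pairs.add((qi, ti))
    return pairs


def oracle_window_join(anchors, others, w):
    kept = set()
    for ai, a in enumerate(anchors):
        aiv = as_interval(a)
        ext = {(aiv.chrom, b) for b in range(max(0, aiv.start - w), aiv.end + w)}
        for o in others:
            if ext & base_set(o):
                kept.add(ai)
                break
    return kept


def oracle_union_bases(records):
    bases = set()
    for r in records:
        bases |= base_set(r)
    return bases


def oracle_bin_counts(window, bin_width, features):
    n_bins = window.length // bin_width
    counts = []
    for i in range(n_bins):
        bin_start = window.start + i * bin_width
        bin_bases = {(window.chrom, b) for b in range(bin_start, bin_start + bin_width)}
        counts.append(sum(1 for ft in features if bin_bases & base_set(ft)))
    return counts


def oracle_tss_overlap(tss_list, elements):
    n = 0
    for tss in tss_list:
        if any(as_interval(el).chrom == tss.chrom
               and as_interval(el).start <= tss.position < as_interval(el).end
               for el in elements):
            n += 1
    return n
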
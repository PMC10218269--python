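"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

from typing import Sequence

import numpy as np

CH = ("CA", "CC", "CT")


def brute_weighted_level(records, context, nc: float = 0.0, region=None):
    """Naive loop over records; returns (raw, corrected) or None if no calls."""
    wanted = CH if context == "CH" else (context,)
    m = t = 0
    for r in records:
        if region is not None:
            if r.chrom != region.chrom or not (region.start <= r.pos < region.end):
                continue
        if r.context in wanted:
            m += r.count_m
            t += r.count_total
    if t == 0:
        return None
    raw = m / t
    return raw, max(0.0, raw - nc)


def brute_enrichment_score(genes: Sequence[str], scores: Sequence[float],
                           gene_set: Sequence[str], p: float = 1.0) -> float:
    """Full O(N) walk down the ranked list; signed extremum of the sum."""
    gene_set = set(gene_set)
    hits = [g in gene_set for g in genes]
    n, k = len(genes), sum(hits)
    denom = sum(abs(s) ** p for s, h in zip(scores, hits) if h)
    run = 0.0
    best = 0.0
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** p / denom) if denom > 0 else 1.0 / k
        else:
            run -= 1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


def brute_metagene_bins(sites, gene, flank_bp, n_body, n_flank):
    """Per-site bin assignment by explicit case analysis; returns
    (bin_index, count_m, count_total) triples for sites within scope."""
    out = []
    fw = flank_bp / n_flank
    for chrom, pos, count_m, count_total in sites:
        if chrom != gene.chrom:
            continue
        rel = pos - gene.start if gene.strand == "+" else (gene.end - 1) - pos
        if -flank_bp <= rel < 0:
            b = min(int((rel + flank_bp) // fw), n_flank - 1)
        elif 0 <= rel < gene.length:
            b = n_flank + min(int(rel / gene.length * n_body), n_body - 1)
        elif gene.length <= rel < gene.length + flank_bp:
            b = n_flank + n_body + min(int((rel - gene.length) // fw), n_flank - 1)
        else:
            continue
        out.append((b, count_m, count_total))
    return out
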
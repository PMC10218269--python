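"""Differentially methylated regions: candidates, filters, enrichment.

Candidate generation is a deliberately simple same-sign-run merger over
per-cytosine level differences (an external segmentation tool's BED can be
supplied instead). The scientific content is in the downstream filters —
at least 3 cytosines, per-sample coverage of at least 5, more than 3
cytosines per 100 bp, and an absolute pooled methylation difference of at
least 0.2 — and in the observed/expected feature enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MethylomeSample, NonconversionRates, _ChromIndex, _context_mask
from .io import GenomicFeature

log = logging.getLogger(__name__)


@dataclass
class Dmr:
    """A filtered differentially methylated region (sample A vs sample B)."""

    chrom: str
    start: int
    end: int
    context: str
    n_cytosines: int
    min_coverage: int          # lowest retained per-site coverage in either sample
    level_a: float
    level_b: float
    delta: float               # level_a - level_b (A = in vitro by convention)
    direction: str             # hyper_in_vitro / hypo_in_vitro
    density: float             # cytosines per 100 bp

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _shared_sites(sample_a: MethylomeSample, sample_b: MethylomeSample,
                  context: str) -> pd.DataFrame:
    """Sites of the context covered (>=1 call) in both samples, merged."""
    def pick(s: MethylomeSample) -> pd.DataFrame:
        mask = _context_mask(s.data["context"], context)
        df = s.data.loc[mask & (s.data["count_total"] > 0),
                        ["chrom", "pos", "count_m", "count_total"]]
        return df
    a, b = pick(sample_a), pick(sample_b)
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("samples share no covered sites in this context")
    merged["level_a"] = merged["count_m_a"] / merged["count_total_a"]
    merged["level_b"] = merged["count_m_b"] / merged["count_total_b"]
    merged["diff"] = merged["level_a"] - merged["level_b"]
    return merged.sort_values(["chrom", "pos"]).reset_index(drop=True)


def candidate_regions(sample_a: MethylomeSample, sample_b: MethylomeSample,
                      context: str, site_delta_min: float = 0.1,
                      max_gap_bp: int = 500, min_sites: int = 3,
                      ) -> list[GenomicFeature]:
    """Merge runs of same-sign per-site differences into candidate intervals.

    A run extends over consecutive shared sites whose difference has the
    same sign and magnitude >= ``site_delta_min``, with gaps <= ``max_gap_bp``;
    runs with >= ``min_sites`` sites become candidates.
    """
    shared = _shared_sites(sample_a, sample_b, context)
    candidates: list[GenomicFeature] = []
    n_cand = 0
    for chrom, grp in shared.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        diff = grp["diff"].to_numpy()
        strong = np.abs(diff) >= site_delta_min
        sign = np.sign(diff)
        run_start = None
        run_sign = 0.0
        prev_pos = None
        count = 0

        def close(end_pos: int) -> None:
            nonlocal n_cand
            if count >= min_sites:
                n_cand += 1
                candidates.append(GenomicFeature(
                    chrom, int(run_start), int(end_pos) + 1,
                    f"cand{n_cand:04d}", "DMR"))

        for i in range(len(pos)):
            breaks = (not strong[i]
                      or (run_start is not None and sign[i] != run_sign)
                      or (prev_pos is not None and pos[i] - prev_pos > max_gap_bp))
            if run_start is not None and breaks:
                close(prev_pos)
                run_start = None
                count = 0
            if strong[i] and run_start is None:
                run_start = pos[i]
                run_sign = sign[i]
                count = 0
            if run_start is not None:
                count += 1
            prev_pos = pos[i]
        if run_start is not None:
            close(prev_pos)
    return candidates


def filter_dmrs(candidates: Sequence[GenomicFeature],
                sample_a: MethylomeSample, sample_b: MethylomeSample,
                context: str, min_sites: int = 3, min_cov: int = 5,
                min_density: float = 3.0, min_delta: float = 0.2,
                coverage_mode: str = "per_site") -> list[Dmr]:
    """Apply the DMR filters to candidate intervals.

    A candidate passes iff (i) it retains >= ``min_sites`` cytosines, where
    in ``per_site`` mode a cytosine is retained only with coverage >=
    ``min_cov`` in each sample (``region_mean`` instead requires the mean
    coverage per sample to reach ``min_cov``); (ii) its retained-site span
    holds more than ``min_density`` cytosines per 100 bp (strict >); and
    (iii) the pooled level difference satisfies |delta| >= ``min_delta``.
    """
    if coverage_mode not in ("per_site", "region_mean"):
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    shared = _shared_sites(sample_a, sample_b, context)
    by_chrom = {c: g.reset_index(drop=True) for c, g in shared.groupby("chrom")}
    dmrs: list[Dmr] = []
    for cand in candidates:
        grp = by_chrom.get(cand.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [cand.start, cand.end])
        sub = grp.iloc[lo:hi]
        if sub.empty:
            continue
        if coverage_mode == "per_site":
            sub = sub[(sub["count_total_a"] >= min_cov)
                      & (sub["count_total_b"] >= min_cov)]
        else:
            if (sub["count_total_a"].mean() < min_cov
                    or sub["count_total_b"].mean() < min_cov):
                continue
        n = len(sub)
        if n < min_sites:
            continue
        start = int(sub["pos"].min())
        end = int(sub["pos"].max()) + 1
        density = n / ((end - start) / 100.0)
        if density <= min_density:
            continue
        level_a = sub["count_m_a"].sum() / sub["count_total_a"].sum()
        level_b = sub["count_m_b"].sum() / sub["count_total_b"].sum()
        delta = level_a - level_b
        if abs(delta) < min_delta:
            continue
        dmrs.append(Dmr(
            chrom=cand.chrom, start=start, end=end, context=context,
            n_cytosines=n,
            min_coverage=int(min(sub["count_total_a"].min(),
                                 sub["count_total_b"].min())),
            level_a=float(level_a), level_b=float(level_b), delta=float(delta),
            direction="hyper_in_vitro" if delta > 0 else "hypo_in_vitro",
            density=float(density)))
    return dmrs


def _merged_intervals(features: Sequence[GenomicFeature],
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays for midpoint lookups."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        per_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    out = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def class_length(features: Sequence[GenomicFeature]) -> int:
    """Total genomic span of a feature class after merging overlaps."""
    return int(sum((e - s).sum() for s, e in _merged_intervals(features).values()))


def _midpoint_in(features_index, chrom: str, midpoint: int) -> bool:
    if chrom not in features_index:
        return False
    starts, ends = features_index[chrom]
    i = int(np.searchsorted(starts, midpoint, side="right")) - 1
    return i >= 0 and midpoint < ends[i]


def feature_enrichment(dmrs: Sequence[Dmr],
                       feature_classes: Mapping[str, Sequence[GenomicFeature]],
                       genome_length: int) -> pd.DataFrame:
    """Observed/expected DMR enrichment per feature class (midpoint rule).

    expected = total DMRs x (merged class length / genome length);
    enrichment = observed / expected. Classes with zero length are omitted
    with a warning. Hyper/hypo direction counts are reported per class.
    """
    total = len(dmrs)
    rows = []
    for cls_name, features in feature_classes.items():
        length = class_length(features)
        if length == 0:
            log.warning("feature class %r has zero length; omitted", cls_name)
            continue
        index = _merged_intervals(features)
        inside = [d for d in dmrs if _midpoint_in(index, d.chrom, d.midpoint)]
        expected = total * length / genome_length
        rows.append({
            "feature_class": cls_name,
            "observed": len(inside),
            "expected": expected,
            "enrichment": len(inside) / expected if expected > 0 else np.nan,
            "hyper": sum(d.direction == "hyper_in_vitro" for d in inside),
            "hypo": sum(d.direction == "hypo_in_vitro" for d in inside),
            "class_length": length,
        })
    return pd.DataFrame(rows)


def developmental_dmr_status(sample: MethylomeSample,
                             dev_dmrs: Sequence[GenomicFeature], context: str,
                             nonconversion: NonconversionRates | None = None,
                             hypo_lo: float = 1 / 3, hyper_hi: float = 2 / 3,
                             ) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Classify a sample's corrected level in developmental DMRs.

    Each region's level is binned {low, intermediate, high} by the two cut
    points; regions without covered cytosines are missing. The summary
    gives, per developmental class (fetal/adult), the fraction of covered
    regions in each state.
    """
    index = _ChromIndex(sample, context)
    nc = nonconversion.rate(context) if nonconversion is not None else 0.0
    rows = []
    for f in dev_dmrs:
        pooled = index.pooled(f)
        if pooled is None or pooled[1] == 0:
            level, status = np.nan, "missing"
        else:
            m, t, _n = pooled
            level = max(0.0, m / t - nc)
            status = ("low" if level < hypo_lo
                      else "high" if level > hyper_hi else "intermediate")
        rows.append({"name": f.name, "dev_class": f.feature_type,
                     "chrom": f.chrom, "start": f.start, "end": f.end,
                     "level": level, "status": status})
    table = pd.DataFrame(rows)
    summary: dict[str, dict[str, float]] = {}
    for dev_class, grp in table.groupby("dev_class"):
        covered = grp[grp["status"] != "missing"]
        if covered.empty:
            log.warning("developmental class %r: no covered regions", dev_class)
            summary[dev_class] = {}
            continue
        summary[dev_class] = {
            s: float((covered["status"] == s).sum()) / len(covered)
            for s in ("low", "intermediate", "high")}
    return table, summary


def dmrs_to_features(dmrs: Sequence[Dmr]) -> list[GenomicFeature]:
    return [GenomicFeature(d.chrom, d.start, d.end,
                           f"{d.direction}_{i + 1:04d}", "DMR")
            for i, d in enumerate(dmrs)]
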
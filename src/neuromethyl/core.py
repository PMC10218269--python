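"""Weighted methylation levels with spike-in nonconversion correction.

The weighted methylation level of a scope (genome, feature, bin) and
context is the pooled count of methylated basecalls divided by the pooled
total basecalls at reference cytosines of that context — never a mean of
per-site or per-part levels. Bisulfite nonconversion, estimated per context
from a fully unmethylated spike-in genome, is subtracted from the raw
level and the result clipped at zero.

The CH super-context pools CA+CC+CT counts before division, and its
nonconversion rate is the pooled spike-in rate over those three contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CH_SUBCONTEXTS, CONTEXTS, CytosineRecord, GenomicFeature

log = logging.getLogger(__name__)

#: default per-feature coverage floor for matrix inclusion
DEFAULT_MIN_CALLS = 20


class MethylomeSample:
    """A named methylome: per-cytosine counts held as a sorted table.

    Parameters
    ----------
    name : sample identifier
    data : DataFrame with columns chrom, pos, strand, context, count_m,
        count_total (extra columns are preserved)
    group : optional biological group label (e.g. ``invitro_neuron``)
    """

    REQUIRED = ("chrom", "pos", "strand", "context", "count_m", "count_total")

    def __init__(self, name: str, data: pd.DataFrame, group: str | None = None):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"sample {name!r}: missing columns {missing}")
        if (data["count_m"] > data["count_total"]).any() or (data["count_m"] < 0).any():
            raise ValueError(f"sample {name!r}: counts must satisfy 0 <= m <= total")
        bad = set(data["context"].unique()) - set(CONTEXTS)
        if bad:
            raise ValueError(f"sample {name!r}: unknown contexts {sorted(bad)}")
        self.name = name
        self.group = group
        self.data = data.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self._by_chrom: dict[str, pd.DataFrame] | None = None

    @classmethod
    def from_records(cls, name: str, records: Iterable[CytosineRecord],
                     group: str | None = None) -> "MethylomeSample":
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(name, df, group=group)

    def records(self) -> list[CytosineRecord]:
        return [CytosineRecord(*row) for row in
                self.data[list(self.REQUIRED)].itertuples(index=False, name=None)]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data["chrom"].unique())

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        """Per-chromosome slice, position-sorted (cached)."""
        if self._by_chrom is None:
            self._by_chrom = {c: g.reset_index(drop=True)
                              for c, g in self.data.groupby("chrom", sort=False)}
        try:
            return self._by_chrom[chrom]
        except KeyError:
            return self.data.iloc[0:0]

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"MethylomeSample({self.name!r}, sites={len(self)}, group={self.group!r})"


def _context_mask(contexts: pd.Series, context: str) -> np.ndarray:
    if context == "CH":
        return contexts.isin(CH_SUBCONTEXTS).to_numpy()
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    return (contexts == context).to_numpy()


@dataclass
class NonconversionRates:
    """Per-context false-methylation rates estimated from the spike-in.

    ``rate("CH")`` is the pooled rate over CA, CC and CT calls.
    """

    m_calls: dict[str, int]
    total_calls: dict[str, int]

    def rate(self, context: str) -> float:
        if context == "CH":
            m = sum(self.m_calls[c] for c in CH_SUBCONTEXTS)
            t = sum(self.total_calls[c] for c in CH_SUBCONTEXTS)
        else:
            m, t = self.m_calls[context], self.total_calls[context]
        if t == 0:
            raise ValueError(f"no spike-in calls for context {context}")
        return m / t

    @property
    def rates(self) -> dict[str, float]:
        return {c: self.rate(c) for c in (*CONTEXTS, "CH")}

    @classmethod
    def zero(cls) -> "NonconversionRates":
        return cls({c: 0 for c in CONTEXTS}, {c: 1 for c in CONTEXTS})


def estimate_nonconversion(spikein: MethylomeSample) -> NonconversionRates:
    """Estimate nonconversion as the spike-in's apparent methylation per context.

    Raises if any of the four contexts has zero total calls; warns if a
    rate exceeds 0.1 (a plausible sign of a contaminated control).
    """
    m_calls: dict[str, int] = {}
    total_calls: dict[str, int] = {}
    for context in CONTEXTS:
        sub = spikein.data[spikein.data["context"] == context]
        m_calls[context] = int(sub["count_m"].sum())
        total_calls[context] = int(sub["count_total"].sum())
        if total_calls[context] == 0:
            raise ValueError(f"spike-in has zero total calls in context {context}")
    nc = NonconversionRates(m_calls, total_calls)
    for context in CONTEXTS:
        if nc.rate(context) > 0.1:
            log.warning("spike-in %s: nonconversion %.3f in %s exceeds 0.1",
                        spikein.name, nc.rate(context), context)
    return nc


@dataclass
class WeightedLevel:
    """Pooled-count methylation level of one context within one scope."""

    context: str
    m_calls: int
    total_calls: int
    raw_level: float
    corrected_level: float
    n_cytosines: int = 0
    missing: bool = False
    reason: str = ""

    @classmethod
    def empty(cls, context: str, reason: str) -> "WeightedLevel":
        return cls(context, 0, 0, float("nan"), float("nan"),
                   n_cytosines=0, missing=True, reason=reason)


def _pool(m: int, t: int, n_sites: int, context: str,
          nonconversion: NonconversionRates | None) -> WeightedLevel:
    if t == 0:
        return WeightedLevel.empty(context, "zero total calls in scope")
    raw = m / t
    nc = nonconversion.rate(context) if nonconversion is not None else 0.0
    return WeightedLevel(context, m, t, raw, max(0.0, raw - nc), n_cytosines=n_sites)


def weighted_level(sample: MethylomeSample, context: str,
                   nonconversion: NonconversionRates | None = None,
                   region: GenomicFeature | None = None) -> WeightedLevel:
    """Weighted methylation level of ``context`` over the sample or a region.

    A zero-call scope yields a missing value (``missing=True``), which is
    distinct from a level of 0.
    """
    if region is None:
        df = sample.data
    else:
        tbl = sample.chrom_table(region.chrom)
        pos = tbl["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [region.start, region.end])
        df = tbl.iloc[lo:hi]
    mask = _context_mask(df["context"], context)
    m = int(df["count_m"].to_numpy()[mask].sum())
    t = int(df["count_total"].to_numpy()[mask].sum())
    return _pool(m, t, int(mask.sum()), context, nonconversion)


class _ChromIndex:
    """Cumulative-sum index for O(log n) pooled counts over intervals."""

    def __init__(self, sample: MethylomeSample, context: str):
        self.chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sample.chroms:
            tbl = sample.chrom_table(chrom)
            mask = _context_mask(tbl["context"], context)
            pos = tbl["pos"].to_numpy()[mask]
            cm = np.concatenate([[0], np.cumsum(tbl["count_m"].to_numpy()[mask])])
            ct = np.concatenate([[0], np.cumsum(tbl["count_total"].to_numpy()[mask])])
            self.chroms[chrom] = (pos, cm, ct)

    def pooled(self, feature: GenomicFeature) -> tuple[int, int, int] | None:
        """(m_calls, total_calls, n_sites) within the feature, or None if the
        chromosome is absent from the sample."""
        if feature.chrom not in self.chroms:
            return None
        pos, cm, ct = self.chroms[feature.chrom]
        lo, hi = np.searchsorted(pos, [feature.start, feature.end])
        return int(cm[hi] - cm[lo]), int(ct[hi] - ct[lo]), int(hi - lo)


def aggregate_by_feature(sample: MethylomeSample, features: Sequence[GenomicFeature],
                         context: str,
                         nonconversion: NonconversionRates | None = None,
                         min_calls: int = DEFAULT_MIN_CALLS) -> pd.DataFrame:
    """Per-feature weighted levels for one sample and context.

    A cytosine overlapping two features contributes to both. Features whose
    pooled total calls fall below ``min_calls`` (or whose chromosome is
    absent) are flagged missing, never zero-filled.
    """
    if min_calls < 1:
        raise ValueError("min_calls must be >= 1")
    index = _ChromIndex(sample, context)
    rows = []
    for f in features:
        pooled = index.pooled(f)
        if pooled is None:
            log.warning("feature %s: chromosome %s absent from sample %s",
                        f.name, f.chrom, sample.name)
            m = t = n = 0
        else:
            m, t, n = pooled
        wl = _pool(m, t, n, context, nonconversion)
        missing = wl.missing or t < min_calls
        rows.append({
            "name": f.name, "chrom": f.chrom, "start": f.start, "end": f.end,
            "context": context, "m_calls": m, "total_calls": t, "n_cytosines": n,
            "raw_level": np.nan if missing else wl.raw_level,
            "corrected_level": np.nan if missing else wl.corrected_level,
            "missing": missing,
        })
    return pd.DataFrame(rows)


class GeneMethylationMatrix:
    """Long-format gene x sample x context table of corrected levels.

    Entries below the coverage floor are NaN (missing), never 0.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table  # columns: gene, sample, context, corrected_level,
        #                     raw_level, m_calls, total_calls, n_cytosines, missing

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique())

    def levels(self, context: str) -> pd.DataFrame:
        """Genes x samples pivot of corrected levels (NaN where missing)."""
        sub = self.table[self.table["context"] == context]
        return sub.pivot(index="gene", columns="sample", values="corrected_level")

    def calls(self, context: str) -> pd.DataFrame:
        sub = self.table[self.table["context"] == context]
        return sub.pivot(index="gene", columns="sample", values="total_calls")


def build_gene_matrix(samples: Mapping[str, MethylomeSample],
                      genes: Sequence[GenomicFeature],
                      contexts: Sequence[str] = ("CG", "CH"),
                      nonconversion: Mapping[str, NonconversionRates] | None = None,
                      min_calls: int = DEFAULT_MIN_CALLS) -> GeneMethylationMatrix:
    """Aggregate gene-body levels for several samples into one matrix."""
    frames = []
    for name, sample in samples.items():
        nc = nonconversion.get(name) if nonconversion else None
        for context in contexts:
            df = aggregate_by_feature(sample, genes, context, nc, min_calls)
            df = df.rename(columns={"name": "gene"})
            df.insert(1, "sample", name)
            frames.append(df[["gene", "sample", "context", "corrected_level",
                              "raw_level", "m_calls", "total_calls",
                              "n_cytosines", "missing"]])
    return GeneMethylationMatrix(pd.concat(frames, ignore_index=True))


def metagene_profile(sample: MethylomeSample, genes: Sequence[GenomicFeature],
                     context: str,
                     nonconversion: NonconversionRates | None = None,
                     flank_bp: int = 10_000, n_body_bins: int = 60,
                     n_flank_bins: int = 20) -> pd.DataFrame:
    """Pooled metagene profile: upstream flank, scaled gene body, downstream flank.

    Bins run 5'->3' (TSS to TES); minus-strand genes are reversed. Per-bin
    levels pool counts across genes (weighted level, not a mean of genes).
    Returns a DataFrame indexed by bin with columns segment, m_calls,
    total_calls, raw_level, corrected_level.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    n_bins = n_body_bins + 2 * n_flank_bins
    m = np.zeros(n_bins, dtype=np.int64)
    t = np.zeros(n_bins, dtype=np.int64)
    flank_width = flank_bp / n_flank_bins
    for gene in genes:
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.name}: metagene profiles need a strand")
        tbl = sample.chrom_table(gene.chrom)
        pos_all = tbl["pos"].to_numpy()
        lo, hi = np.searchsorted(pos_all, [gene.start - flank_bp, gene.end + flank_bp])
        sub = tbl.iloc[lo:hi]
        mask = _context_mask(sub["context"], context)
        pos = sub["pos"].to_numpy()[mask]
        cm = sub["count_m"].to_numpy()[mask]
        ct = sub["count_total"].to_numpy()[mask]
        if gene.strand == "+":
            rel = pos.astype(float) - gene.start
        else:  # reverse so coordinates run TSS->TES
            rel = (gene.end - 1) - pos.astype(float)
        length = gene.length
        bins = np.empty(len(pos), dtype=np.int64)
        up = rel < 0
        body = (rel >= 0) & (rel < length)
        down = rel >= length
        bins[up] = np.minimum(
            np.floor((rel[up] + flank_bp) / flank_width), n_flank_bins - 1
        ).astype(np.int64)
        bins[body] = n_flank_bins + np.minimum(
            np.floor(rel[body] / length * n_body_bins), n_body_bins - 1
        ).astype(np.int64)
        bins[down] = n_flank_bins + n_body_bins + np.minimum(
            np.floor((rel[down] - length) / flank_width), n_flank_bins - 1
        ).astype(np.int64)
        np.add.at(m, bins, cm)
        np.add.at(t, bins, ct)
    nc = nonconversion.rate(context) if nonconversion is not None else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(t > 0, m / np.maximum(t, 1), np.nan)
    corrected = np.where(np.isnan(raw), np.nan, np.maximum(0.0, raw - nc))
    segment = (["upstream"] * n_flank_bins + ["body"] * n_body_bins
               + ["downstream"] * n_flank_bins)
    return pd.DataFrame({
        "segment": segment, "m_calls": m, "total_calls": t,
        "raw_level": raw, "corrected_level": corrected,
    }, index=pd.RangeIndex(n_bins, name="bin"))


#: the six scopes reported in the per-feature-class summary
FEATURE_CLASSES = ("whole_genome", "intergenic", "introns", "exons", "CGI", "TSS_window")


def feature_class_summary(sample: MethylomeSample,
                          feature_classes: Mapping[str, Sequence[GenomicFeature]],
                          context: str,
                          nonconversion: NonconversionRates | None = None) -> pd.DataFrame:
    """Corrected weighted level per genomic feature class.

    ``feature_classes`` must provide intergenic, introns, exons, CGI and
    TSS_window; the whole-genome row pools every site of the context.
    """
    needed = [c for c in FEATURE_CLASSES if c != "whole_genome"]
    absent = [c for c in needed if c not in feature_classes]
    if absent:
        raise ValueError(f"missing feature classes: {absent}")
    rows = []
    wl = weighted_level(sample, context, nonconversion)
    rows.append({"feature_class": "whole_genome", "context": context,
                 "m_calls": wl.m_calls, "total_calls": wl.total_calls,
                 "raw_level": wl.raw_level, "corrected_level": wl.corrected_level})
    index = _ChromIndex(sample, context)
    for cls_name in needed:
        m = t = n = 0
        for f in feature_classes[cls_name]:
            pooled = index.pooled(f)
            if pooled is not None:
                m += pooled[0]
                t += pooled[1]
                n += pooled[2]
        wl = _pool(m, t, n, context, nonconversion)
        rows.append({"feature_class": cls_name, "context": context,
                     "m_calls": wl.m_calls, "total_calls": wl.total_calls,
                     "raw_level": wl.raw_level, "corrected_level": wl.corrected_level})
    return pd.DataFrame(rows)
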
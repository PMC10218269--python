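"""In vitro vs in vivo methylome comparison.

Per-gene deltas and hyper/hypo classification, heatmap ordering,
normalisation to the global level, 100 kb genome-bin matrices and their
Spearman-correlation hierarchical clustering, and the cross-context
correlation of per-gene deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core import (DEFAULT_MIN_CALLS, GeneMethylationMatrix, MethylomeSample,
                   NonconversionRates, aggregate_by_feature, weighted_level)
from .io import GenomicFeature

#: classification thresholds on the per-gene delta, by context
DEFAULT_DELTA_THRESHOLDS = {"CG": 0.1, "CH": 0.01}


def gene_deltas(matrix: GeneMethylationMatrix, sample_a: str, sample_b: str,
                context: str) -> pd.DataFrame:
    """Per-gene ``level(sample_a) - level(sample_b)`` for one context.

    Genes missing in either sample get a NaN delta (class ``missing``).
    By the study's convention sample_a is the in vitro neuron and
    sample_b the in vivo neuron, so positive deltas mean hypermethylation
    in vitro.
    """
    levels = matrix.levels(context)
    for s in (sample_a, sample_b):
        if s not in levels.columns:
            raise ValueError(f"unknown sample {s!r}; matrix has {list(levels.columns)}")
    df = pd.DataFrame({
        "gene": levels.index,
        "level_a": levels[sample_a].to_numpy(),
        "level_b": levels[sample_b].to_numpy(),
    })
    df["delta"] = df["level_a"] - df["level_b"]
    df["cls"] = np.where(df["delta"].isna(), "missing", "unclassified")
    return df


def classify_hyper_hypo(deltas: pd.DataFrame, threshold: float,
                        ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify genes as hyper / hypo / neither by a symmetric delta threshold.

    Fractions are over genes with a non-missing delta.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    df = deltas.copy()
    ok = df["delta"].notna()
    if not ok.any():
        raise ValueError("no genes with non-missing deltas")
    df.loc[~ok, "cls"] = "missing"
    df.loc[ok, "cls"] = np.select(
        [df.loc[ok, "delta"] > threshold, df.loc[ok, "delta"] < -threshold],
        ["hyper", "hypo"], default="neither")
    n = int(ok.sum())
    fractions = {c: float((df.loc[ok, "cls"] == c).sum()) / n
                 for c in ("hyper", "hypo", "neither")}
    return df, fractions


def order_for_heatmap(deltas: pd.DataFrame) -> list[str]:
    """Genes sorted by descending delta; ties broken by gene name."""
    ok = deltas[deltas["delta"].notna()]
    ordered = ok.sort_values(["delta", "gene"], ascending=[False, True],
                             kind="mergesort")
    return ordered["gene"].tolist()


def normalize_to_global(gene_levels: pd.Series, global_level: float) -> pd.Series:
    """Per-gene levels divided by the sample's global corrected level."""
    if not np.isfinite(global_level) or global_level <= 0:
        raise ValueError("global level must be positive and finite")
    return gene_levels / global_level


@dataclass
class BinMatrix:
    """Tiling genome bins x samples corrected-level matrix with a usable mask."""

    bins: list[GenomicFeature]
    levels: pd.DataFrame   # index bin name, columns sample names
    mask: pd.DataFrame     # True where the bin is usable for that sample
    calls: pd.DataFrame


def make_bins(chrom_lengths: Mapping[str, int], bin_size: int = 100_000,
              exclude: Sequence[str] = ("chrX", "chrY")) -> list[GenomicFeature]:
    """Non-overlapping tiling bins per autosome; the last bin may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins = []
    for chrom in sorted(chrom_lengths):
        if chrom in exclude:
            continue
        length = chrom_lengths[chrom]
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            bins.append(GenomicFeature(chrom, start, end,
                                       f"{chrom}:{start}-{end}", "bin"))
    return bins


def bin_genome(samples: Mapping[str, MethylomeSample],
               chrom_lengths: Mapping[str, int], context: str,
               nonconversion: Mapping[str, NonconversionRates] | None = None,
               bin_size: int = 100_000, exclude: Sequence[str] = ("chrX", "chrY"),
               min_calls: int = DEFAULT_MIN_CALLS) -> BinMatrix:
    """Corrected weighted level per tiling bin and sample."""
    bins = make_bins(chrom_lengths, bin_size, exclude)
    levels, mask, calls = {}, {}, {}
    for name in sorted(samples):
        nc = nonconversion.get(name) if nonconversion else None
        df = aggregate_by_feature(samples[name], bins, context, nc, min_calls)
        levels[name] = df["corrected_level"].to_numpy()
        mask[name] = ~df["missing"].to_numpy()
        calls[name] = df["total_calls"].to_numpy()
    index = [b.name for b in bins]
    bm = BinMatrix(bins,
                   pd.DataFrame(levels, index=index),
                   pd.DataFrame(mask, index=index),
                   pd.DataFrame(calls, index=index))
    if not bm.mask.to_numpy().any():
        raise ValueError("all bins are masked (coverage below min_calls everywhere)")
    return bm


@dataclass
class ClusteringResult:
    """Sample clustering on bin levels: correlations, linkage and tree."""

    correlation: pd.DataFrame     # pairwise Spearman rho
    linkage: np.ndarray           # scipy linkage matrix (average, 1 - rho)
    newick: str
    merges: list[frozenset[str]]  # leaf-name sets in merge order

    @property
    def first_merge(self) -> frozenset[str]:
        return self.merges[0]


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def correlation_clustering(bin_matrix: BinMatrix) -> ClusteringResult:
    """Average-linkage clustering of samples at distance 1 - Spearman rho.

    Each pairwise rho uses the bins unmasked in both samples. Output is
    deterministic and invariant to sample and bin input order (samples are
    ordered by name internally).
    """
    names = sorted(bin_matrix.levels.columns)
    if len(names) < 2:
        raise ValueError("need >= 2 samples to cluster")
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = (bin_matrix.mask[a] & bin_matrix.mask[b]).to_numpy()
            if shared.sum() < 3:
                raise ValueError(f"samples {a}/{b}: fewer than 3 shared bins")
            xa = bin_matrix.levels[a].to_numpy()[shared]
            xb = bin_matrix.levels[b].to_numpy()[shared]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                bad = a if np.ptp(xa) == 0 else b
                raise ValueError(f"sample {bad!r} has constant bin levels; "
                                 "Spearman correlation undefined")
            r = stats.spearmanr(xa, xb).statistic
            rho.loc[a, b] = rho.loc[b, a] = r
    dist = 1.0 - rho.to_numpy()
    condensed = dist[np.triu_indices(len(names), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(linkage)
    newick = _newick(tree, names) + ";"
    merges: list[frozenset[str]] = []
    members: dict[int, frozenset[str]] = {i: frozenset([n]) for i, n in enumerate(names)}
    for k, (i, j, _d, _n) in enumerate(linkage):
        merged = members[int(i)] | members[int(j)]
        members[len(names) + k] = merged
        merges.append(merged)
    return ClusteringResult(rho, linkage, newick, merges)


def cross_context_correlation(deltas_a: pd.Series, deltas_b: pd.Series,
                              ) -> tuple[float, int]:
    """Pearson r between two per-gene delta vectors over their shared genes.

    Typically called with the CG and CH delta vectors of the same sample
    pair; a low r indicates the two contexts diverge on different genes.
    """
    shared = deltas_a.dropna().index.intersection(deltas_b.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes with both deltas")
    x = deltas_a.loc[shared].to_numpy(dtype=float)
    y = deltas_b.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a delta vector")
    return float(stats.pearsonr(x, y).statistic), int(len(shared))
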
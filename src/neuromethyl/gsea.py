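"""Per-gene methylation similarity score and from-scratch preranked GSEA.

The similarity score combines (i) how close the two neuron samples'
gene-body methylation is (``s_neuron = |y - 1|`` where y is the absolute
per-gene difference) and (ii) how far the neuron mean is from the mean of
the non-neuronal samples (glia, fetal). The two components are averaged
and min-max rescaled over the scored genes to [0, 1].

GSEA uses the classic weighted Kolmogorov-Smirnov running sum: walking
down the ranked list, a hit increments by |score|^p / sum_set |score|^p
and a miss decrements by 1 / (N - N_set); the enrichment score ES is the
signed extremum of the walk. NES normalises ES by the mean |null ES| of
matching sign over random same-size gene samples, and the permutation
p-value uses the add-one rule within the matching sign class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes ordered best-first with their ranking scores."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(values: pd.Series | Mapping[str, float],
               descending: bool = True) -> RankedGeneList:
    """Stable sort of genes by score; ties broken lexicographically by name."""
    s = pd.Series(values, dtype=float)
    if s.index.duplicated().any():
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene names: {dups}")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("ranking values must be finite")
    df = s.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[not descending, True],
                        kind="mergesort")
    return RankedGeneList(df["gene"].tolist(), df["score"].to_numpy())


def similarity_score(level_invivo: pd.Series, level_invitro: pd.Series,
                     level_glia: pd.Series, level_fetal: pd.Series,
                     scale: str = "minmax") -> pd.DataFrame:
    """Combined neuron-similarity / non-neuron-dissimilarity score per gene.

    y = |invitro - invivo|; s_neuron = |y - 1|;
    s_distinct = |mean(neurons) - mean(glia, fetal)|;
    combined_raw = (s_neuron + s_distinct) / 2;
    combined = min-max rescale of combined_raw over the scored genes
    (``scale="none"`` keeps the raw mean).

    Genes with any missing level are excluded (logged). The score is
    symmetric in the two neuron samples and in glia vs fetal.
    """
    levels = pd.DataFrame({"invivo": level_invivo, "invitro": level_invitro,
                           "glia": level_glia, "fetal": level_fetal})
    scored = levels.dropna()
    dropped = len(levels) - len(scored)
    if dropped:
        log.info("similarity score: excluded %d genes with missing levels", dropped)
    if scored.empty:
        raise ValueError("no genes with all four levels present")
    y = (scored["invitro"] - scored["invivo"]).abs()
    s_neuron = (y - 1.0).abs()
    neuron_mean = (scored["invivo"] + scored["invitro"]) / 2.0
    other_mean = (scored["glia"] + scored["fetal"]) / 2.0
    s_distinct = (neuron_mean - other_mean).abs()
    combined_raw = (s_neuron + s_distinct) / 2.0
    if scale == "minmax":
        lo, hi = combined_raw.min(), combined_raw.max()
        if hi > lo:
            combined = (combined_raw - lo) / (hi - lo)
        else:
            log.warning("similarity score: constant combined score; "
                        "min-max rescale degenerate, using 0.5")
            combined = pd.Series(0.5, index=combined_raw.index)
    elif scale == "none":
        combined = combined_raw
    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = pd.DataFrame({"s_neuron": s_neuron, "s_distinct": s_distinct,
                        "combined_raw": combined_raw, "combined": combined})
    out.index.name = "gene"
    return out


def _hit_walk_extremum(hit_pos: np.ndarray, hit_w: np.ndarray, n: int,
                       ) -> tuple[float, int]:
    """Signed extremum of the KS running sum given sorted hit positions.

    hit_w are normalised hit increments (sum 1); misses decrement by
    1/(n - k). The walk is piecewise linear between hits, so candidate
    extrema are the values just before and just after each hit.
    """
    k = len(hit_pos)
    miss = 1.0 / (n - k)
    cum_w = np.cumsum(hit_w)
    j = np.arange(1, k + 1)
    after = cum_w - (hit_pos + 1 - j) * miss       # sum just after hit j
    before = (cum_w - hit_w) - (hit_pos - (j - 1)) * miss  # just before hit j
    hi_idx = int(np.argmax(after))
    lo_idx = int(np.argmin(before))
    hi, lo = float(after[hi_idx]), float(before[lo_idx])
    if hi >= -lo:
        return hi, int(hit_pos[hi_idx])
    return lo, int(hit_pos[lo_idx])


def _es_from_positions(positions: np.ndarray, abs_scores: np.ndarray,
                       n: int, weight_exponent: float) -> tuple[float, int]:
    positions = np.sort(positions)
    w = abs_scores[positions] ** weight_exponent
    total = w.sum()
    if total > 0:
        w = w / total
    else:  # all-zero scores in the set: unweighted hits
        w = np.full(len(positions), 1.0 / len(positions))
    return _hit_walk_extremum(positions, w, n)


@dataclass
class EnrichmentScore:
    es: float
    peak_index: int  # 0-based rank position of the extremum


def enrichment_score(ranked: RankedGeneList, gene_set: Sequence[str],
                     weight_exponent: float = 1.0) -> EnrichmentScore:
    """ES of one gene set against a ranked list (signed walk extremum)."""
    index = ranked.index
    positions = np.array(sorted(index[g] for g in set(gene_set) if g in index))
    n = len(ranked)
    if len(positions) == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if len(positions) == n:
        raise ValueError("gene set covers the entire ranked list")
    es, peak = _es_from_positions(positions, np.abs(ranked.scores), n,
                                  weight_exponent)
    return EnrichmentScore(es, peak)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    size: int
    leading_edge: list[str] = field(default_factory=list)


@dataclass
class GseaOutput:
    """All tested sets (NES-descending) plus the p-filtered subset."""

    table: pd.DataFrame
    significant: pd.DataFrame
    n_perm: int


def _null_es(n: int, sizes: Sequence[int], abs_scores: np.ndarray,
             n_perm: int, weight_exponent: float,
             rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Permutation null ES per distinct set size (shared across equal sizes)."""
    nulls: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        es = np.empty(n_perm)
        for i in range(n_perm):
            positions = rng.choice(n, size=k, replace=False)
            es[i], _ = _es_from_positions(positions, abs_scores, n, weight_exponent)
        nulls[k] = es
    return nulls


def gsea_preranked(ranked: RankedGeneList, collection: Mapping[str, Sequence[str]],
                   n_perm: int = 1000, seed: int | None = None,
                   weight_exponent: float = 1.0, min_size: int = 5,
                   max_size: int = 500, p_filter: float = 0.05) -> GseaOutput:
    """Preranked GSEA over a gene-set collection with a permutation null.

    NES = ES / mean(|null ES| of matching sign); p-value uses the add-one
    rule within the matching sign class. The null is built once per
    distinct set size from random same-size samples of the ranked list.
    Results with p < ``p_filter`` form the ``significant`` table; both
    tables are sorted by descending NES. Deterministic for a fixed seed.
    """
    index = ranked.index
    n = len(ranked)
    kept: dict[str, np.ndarray] = {}
    for name, genes in collection.items():
        positions = np.array(sorted({index[g] for g in genes if g in index}),
                             dtype=int)
        if min_size <= len(positions) <= min(max_size, n - 1):
            kept[name] = positions
    if not kept:
        raise ValueError("no gene set passes the size filter")
    abs_scores = np.abs(ranked.scores)
    rng = np.random.default_rng(seed)
    nulls = _null_es(n, [len(p) for p in kept.values()], abs_scores,
                     n_perm, weight_exponent, rng)
    rows = []
    for name, positions in kept.items():
        es, peak = _es_from_positions(positions, abs_scores, n, weight_exponent)
        null = nulls[len(positions)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
        else:  # add-one permutation p within the matching sign class
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else np.nan
            extreme = int((np.abs(same_sign) >= abs(es)).sum())
            p = (1 + extreme) / (1 + len(same_sign))
        if es >= 0:
            edge = [ranked.genes[i] for i in sorted(positions) if i <= peak]
        else:
            edge = [ranked.genes[i] for i in sorted(positions) if i >= peak]
        rows.append({"set_name": name, "es": es, "nes": nes, "p_value": p,
                     "size": len(positions), "n_null_same_sign": len(same_sign),
                     "leading_edge": edge})
    table = pd.DataFrame(rows).sort_values("nes", ascending=False,
                                           kind="mergesort").reset_index(drop=True)
    significant = table[table["p_value"] < p_filter].reset_index(drop=True)
    return GseaOutput(table, significant, n_perm)
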
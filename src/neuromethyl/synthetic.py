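"""Synthetic multi-group methylome generator.

Emulates the statistical structure of a whole-genome bisulfite experiment
over an in vitro neuronal differentiation panel: per-cytosine basecall
counts at ~30x coverage for six biological groups (ESC, NPC, in vitro
neuron, in vivo neuron, glia, fetal cortex), a fully unmethylated
lambda-like spike-in, planted differentially methylated regions, and TPM
expression anticorrelated with gene-body mCH.

Observation model per cytosine site::

    depth   ~ Poisson(depth_mean)
    p_obs   = p_true + (1 - p_true) * nonconversion
    count_m ~ Binomial(depth, p_obs)

so the spike-in (p_true = 0) reads out the nonconversion rate, and the
subtraction-based correction recovers p_true * (1 - nonconversion).

Group methylation set-points mirror the global levels measured across the
differentiation panel (e.g. in vitro neuron mCA/CA 0.053, ESC mCA/CA
0.0125, glia/fetal mCH below 0.001).

Randomness is organised as one pseudo-random stream per (purpose, sample,
chromosome), each seeded from the master seed plus stable label hashes, so
output is reproducible regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import MethylomeSample
from .io import CH_SUBCONTEXTS, CONTEXTS, GenomicFeature

# share of simulated cytosine sites per context (CH total 0.84; of the CH
# share, CA:CC:CT = 0.45:0.25:0.30, roughly genome-like)
CONTEXT_WEIGHTS = {"CG": 0.16, "CA": 0.378, "CC": 0.21, "CT": 0.252}
_W_CH = {c: CONTEXT_WEIGHTS[c] / sum(CONTEXT_WEIGHTS[k] for k in CH_SUBCONTEXTS)
         for c in CH_SUBCONTEXTS}


def _tag(*labels: str | int) -> list[int]:
    """Stable 32-bit hashes for seeding named random streams."""
    return [zlib.crc32(str(x).encode()) for x in labels]


def _rng(seed: int, *labels: str | int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *_tag(*labels)]))


@dataclass(frozen=True)
class GroupProfile:
    """True methylation set-points of one biological group.

    mch_global is the pooled CH level; mca_share is the fraction of
    methylated CH calls carried by the CA context. mcg_regional_sd adds a
    group-private regional (per-block) CG deviation, off by default.
    """

    mcg_gene_body: float
    mcg_cgi: float
    mch_global: float
    mca_share: float
    mcg_regional_sd: float = 0.0

    def ch_probabilities(self) -> dict[str, float]:
        """Implied per-subcontext true methylation probabilities."""
        p_ca = self.mch_global * self.mca_share / _W_CH["CA"]
        rest = self.mch_global * (1.0 - self.mca_share) / (_W_CH["CC"] + _W_CH["CT"])
        probs = {"CA": p_ca, "CC": rest, "CT": rest}
        for c, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"implied {c} probability {p:.4f} outside [0, 1]")
        return probs


def _neuron_profile(mca: float, share: float, mcg: float, mcg_cgi: float,
                    **kw) -> GroupProfile:
    return GroupProfile(mcg_gene_body=mcg, mcg_cgi=mcg_cgi,
                        mch_global=mca * _W_CH["CA"] / share, mca_share=share, **kw)


#: global set-points per differentiation group (mCA: in vitro neuron 0.053,
#: in vivo neuron 0.045, ESC 0.0125, NPC 0.008; glia/fetal mCH < 0.001)
DEFAULT_GROUP_PROFILES: dict[str, GroupProfile] = {
    "esc": _neuron_profile(0.0125, 0.70, 0.80, 0.10),
    "npc": _neuron_profile(0.008, 0.70, 0.78, 0.09),
    "invitro_neuron": _neuron_profile(0.053, 0.80, 0.86, 0.15),
    "invivo_neuron": _neuron_profile(0.045, 0.80, 0.79, 0.10),
    "glia": GroupProfile(0.77, 0.08, 0.0008, 0.50),
    "fetal": GroupProfile(0.75, 0.08, 0.0006, 0.50),
}


class DmrPlant(NamedTuple):
    """A region whose true methylation is shifted by delta in sample B."""

    chrom: str
    start: int
    end: int
    context: str  # CG, CA, CC, CT or CH
    delta: float


@dataclass(frozen=True)
class ExpressionModel:
    """log(TPM + 1) = a + b * gene_body_mCH + Normal(0, sd), b <= 0."""

    a: float = 3.0
    b: float = -30.0
    sd: float = 0.5


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-like defaults.

    depth_mean 30 matches the experiment's average per-cytosine coverage;
    nonconversion 0.005 is a typical lambda spike-in error rate. Regional
    amplitudes are 0 by default (homogeneous methylation within a feature
    class, so analytic binomial standard errors hold); the clustering
    scenario enables them explicitly.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 400_000
    n_genes: int = 120
    exons_per_gene: int = 3
    depth_mean: float = 30.0
    nonconversion: float = 0.005
    site_density: float = 0.12          # cytosine sites per bp, all contexts
    spikein_length: int = 48_502        # lambda-like control genome
    spikein_site_density: float = 0.25
    cgi_fraction: float = 0.6           # fraction of TSSs carrying a CGI
    cgi_halfwidth: int = 300
    n_enhancers: int = 40
    enhancer_length: int = 500
    group_profiles: Mapping[str, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES))
    dmr_plant: Sequence[DmrPlant] = field(default_factory=tuple)
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    # regional (per-block) methylation structure, disabled by default
    regional_block_bp: int = 100_000
    cg_regional_amp: float = 0.0        # additive shared CG block pattern
    ch_regional_amp: float = 0.0        # multiplicative shared CH block pattern

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.nonconversion <= 0.05:
            raise ValueError("nonconversion must be in [0, 0.05]")
        for name, prof in self.group_profiles.items():
            for p in (prof.mcg_gene_body, prof.mcg_cgi, prof.mch_global, prof.mca_share):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"group {name}: probability {p} outside [0, 1]")
            prof.ch_probabilities()  # validates implied sub-context levels

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class GenomeAnnotation:
    """Synthetic genome annotation: genes with exon/intron structure plus
    CGIs, TSS windows, enhancers and the intergenic complement."""

    chrom_lengths: dict[str, int]
    genes: list[GenomicFeature]
    exons: list[GenomicFeature]
    introns: list[GenomicFeature]
    cgis: list[GenomicFeature]
    tss_windows: list[GenomicFeature]
    enhancers: list[GenomicFeature]
    intergenic: list[GenomicFeature]

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def feature_classes(self) -> dict[str, list[GenomicFeature]]:
        return {"intergenic": self.intergenic, "introns": self.introns,
                "exons": self.exons, "CGI": self.cgis,
                "TSS_window": self.tss_windows}


def tss_of(gene: GenomicFeature) -> int:
    return gene.start if gene.strand == "+" else gene.end - 1


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Draw a deterministic annotation: non-overlapping genes with exons,
    CGIs at a fraction of TSSs, 1 kb TSS windows and intergenic enhancers."""
    rng = _rng(config.seed, "annotation")
    margin = 600  # keeps 1 kb TSS windows inside chromosome bounds
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1

    genes: list[GenomicFeature] = []
    exons: list[GenomicFeature] = []
    introns: list[GenomicFeature] = []
    cgis: list[GenomicFeature] = []
    tss_windows: list[GenomicFeature] = []
    enhancers: list[GenomicFeature] = []
    intergenic: list[GenomicFeature] = []

    gene_no = 0
    for chrom, n in zip(config.chrom_names, per_chrom):
        n = int(n)
        lengths = rng.integers(1500, 4001, size=n)
        min_gap = 300
        budget = config.chrom_length - 2 * margin - int(lengths.sum())
        slack = budget - (n + 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"n_genes infeasible: {n} genes do not fit in {chrom} "
                f"({config.chrom_length} bp)")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        gaps = extra + min_gap
        cursor = margin
        prev_end = 0
        for i in range(n):
            cursor += int(gaps[i])
            start, end = cursor, cursor + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            name = f"g{gene_no:04d}"
            gene = GenomicFeature(chrom, start, end, name, "gene", strand)
            genes.append(gene)
            if start > prev_end:
                intergenic.append(GenomicFeature(
                    chrom, prev_end, start, f"ig_{chrom}_{prev_end}", "intergenic"))
            prev_end = end
            # exon/intron structure: 2k-1 alternating segments, exons first/last
            k = config.exons_per_gene
            n_seg = 2 * k - 1
            seg = rng.multinomial(int(lengths[i]) - n_seg * 60,
                                  np.full(n_seg, 1.0 / n_seg)) + 60
            bounds = start + np.concatenate([[0], np.cumsum(seg)])
            for j in range(n_seg):
                ftype = "exon" if j % 2 == 0 else "intron"
                feat = GenomicFeature(chrom, int(bounds[j]), int(bounds[j + 1]),
                                      f"{name}.{ftype}{j // 2 + 1}", ftype, strand)
                (exons if ftype == "exon" else introns).append(feat)
            tss = tss_of(gene)
            tss_windows.append(GenomicFeature(
                chrom, tss - 500, tss + 500, f"{name}.tss", "TSS_window", strand))
            if rng.random() < config.cgi_fraction:
                cgis.append(GenomicFeature(
                    chrom, tss - config.cgi_halfwidth, tss + config.cgi_halfwidth,
                    f"{name}.cgi", "CGI"))
            cursor = end
        if prev_end < config.chrom_length:
            intergenic.append(GenomicFeature(
                chrom, prev_end, config.chrom_length,
                f"ig_{chrom}_{prev_end}", "intergenic"))

    # enhancers: centred in the largest intergenic gaps
    gaps_sorted = sorted(intergenic, key=lambda f: -f.length)
    for i, gap in enumerate(gaps_sorted[: config.n_enhancers]):
        if gap.length < config.enhancer_length + 40:
            break
        mid = gap.midpoint
        enhancers.append(GenomicFeature(
            gap.chrom, mid - config.enhancer_length // 2,
            mid - config.enhancer_length // 2 + config.enhancer_length,
            f"enh{i + 1:03d}", "enhancer"))
    return GenomeAnnotation(dict(config.chrom_lengths), genes, exons, introns,
                            cgis, tss_windows, enhancers, intergenic)


def _layout(config: SimulationConfig, chrom: str, length: int,
            density: float) -> pd.DataFrame:
    """Fixed per-chromosome site layout (positions, contexts, strands),
    shared by every sample at a given master seed."""
    rng = _rng(config.seed, "layout", chrom)
    n_sites = int(round(length * density))
    pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
    ctx = rng.choice(CONTEXTS, size=len(pos),
                     p=[CONTEXT_WEIGHTS[c] for c in CONTEXTS])
    strand = rng.choice(["+", "-"], size=len(pos))
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand, "context": ctx})


def _in_intervals(pos: np.ndarray, features: Sequence[GenomicFeature]) -> np.ndarray:
    """Membership mask of positions in a set of disjoint intervals."""
    if not features:
        return np.zeros(len(pos), dtype=bool)
    starts = np.array([f.start for f in features])
    ends = np.array([f.end for f in features])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    idx = np.maximum(idx, 0)
    return ok & (pos < ends[idx])


def _true_probabilities(config: SimulationConfig, annotation: GenomeAnnotation,
                        group: str, chrom: str, layout: pd.DataFrame) -> np.ndarray:
    profile = config.group_profiles[group]
    pos = layout["pos"].to_numpy()
    ctx = layout["context"].to_numpy()
    p = np.empty(len(pos), dtype=float)
    ch_probs = profile.ch_probabilities()
    for c in CH_SUBCONTEXTS:
        p[ctx == c] = ch_probs[c]
    cg = ctx == "CG"
    cgi_here = [f for f in annotation.cgis if f.chrom == chrom]
    in_cgi = _in_intervals(pos, cgi_here)
    p[cg & ~in_cgi] = profile.mcg_gene_body
    p[cg & in_cgi] = profile.mcg_cgi

    block = pos // config.regional_block_bp
    n_blocks = int(block.max()) + 1 if len(block) else 0
    if config.cg_regional_amp > 0 and n_blocks:
        z = np.clip(_rng(config.seed, "region-cg", chrom).standard_normal(n_blocks),
                    -2.0, 2.0)
        p[cg] = p[cg] + config.cg_regional_amp * z[block[cg]]
    if config.ch_regional_amp > 0 and n_blocks:
        z = np.clip(_rng(config.seed, "region-ch", chrom).standard_normal(n_blocks),
                    -2.0, 2.0)
        p[~cg] = p[~cg] * (1.0 + config.ch_regional_amp * z[block[~cg]])
    if profile.mcg_regional_sd > 0 and n_blocks:
        z = np.clip(_rng(config.seed, "region-own", group, chrom)
                    .standard_normal(n_blocks), -2.0, 2.0)
        p[cg] = p[cg] + profile.mcg_regional_sd * z[block[cg]]
    return np.clip(p, 0.0, 1.0)


def _observe(p_true: np.ndarray, config: SimulationConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(config.depth_mean, size=len(p_true))
    p_obs = p_true + (1.0 - p_true) * config.nonconversion
    count_m = rng.binomial(depth, p_obs)
    return count_m, depth


def simulate_methylome(config: SimulationConfig, annotation: GenomeAnnotation,
                       group: str, sample_name: str | None = None,
                       ) -> tuple[MethylomeSample, MethylomeSample]:
    """Simulate one sample of a group plus its unmethylated spike-in.

    Returns ``(sample, spikein)``; the sample's table carries the hidden
    ``p_true`` column used by DMR planting and recovery tests.
    """
    if group not in config.group_profiles:
        raise ValueError(f"unknown group {group!r}; have "
                         f"{sorted(config.group_profiles)}")
    name = sample_name or group
    frames = []
    for chrom, length in annotation.chrom_lengths.items():
        layout = _layout(config, chrom, length, config.site_density)
        p_true = _true_probabilities(config, annotation, group, chrom, layout)
        rng = _rng(config.seed, "counts", name, chrom)
        count_m, depth = _observe(p_true, config, rng)
        df = layout.copy()
        df["count_m"] = count_m
        df["count_total"] = depth
        df["p_true"] = p_true
        frames.append(df)
    sample = MethylomeSample(name, pd.concat(frames, ignore_index=True), group=group)

    sl = _layout(config, "chrL", config.spikein_length, config.spikein_site_density)
    sl = sl.assign(chrom="chrL")
    p0 = np.zeros(len(sl))
    rng = _rng(config.seed, "counts", name, "chrL-spikein")
    count_m, depth = _observe(p0, config, rng)
    sl["count_m"] = count_m
    sl["count_total"] = depth
    sl["p_true"] = 0.0
    spike = MethylomeSample(f"{name}_spikein", sl, group=group)
    return sample, spike


def plant_dmrs(methylome_pair: tuple[MethylomeSample, MethylomeSample],
               dmr_plant: Sequence[DmrPlant], config: SimulationConfig,
               ) -> tuple[MethylomeSample, list[GenomicFeature]]:
    """Shift the true methylation of sample B inside each planted region.

    Counts at affected sites are redrawn at the shifted probability
    (clipped to [0, 1]) using the same depths. Returns the modified
    sample B and the truth features; overlapping plants are an error.
    """
    _, sample_b = methylome_pair
    by_chrom: dict[str, list[DmrPlant]] = {}
    for plant in dmr_plant:
        by_chrom.setdefault(plant.chrom, []).append(plant)
    for chrom, plants in by_chrom.items():
        plants.sort(key=lambda p: p.start)
        for a, b in zip(plants, plants[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping planted regions on {chrom}: "
                                 f"{a.start}-{a.end} and {b.start}-{b.end}")
    data = sample_b.data.copy()
    if "p_true" not in data.columns:
        raise ValueError("plant_dmrs needs the synthetic p_true column")
    truth: list[GenomicFeature] = []
    for i, plant in enumerate(dmr_plant):
        if plant.context == "CH":
            ctx_mask = data["context"].isin(CH_SUBCONTEXTS)
        else:
            ctx_mask = data["context"] == plant.context
        mask = ((data["chrom"] == plant.chrom) & ctx_mask
                & (data["pos"] >= plant.start) & (data["pos"] < plant.end))
        idx = np.flatnonzero(mask.to_numpy())
        p_new = np.clip(data.loc[mask, "p_true"].to_numpy() + plant.delta, 0.0, 1.0)
        p_obs = p_new + (1.0 - p_new) * config.nonconversion
        rng = _rng(config.seed, "plant", sample_b.name, i)
        data.iloc[idx, data.columns.get_loc("count_m")] = rng.binomial(
            data.loc[mask, "count_total"].to_numpy(), p_obs)
        data.iloc[idx, data.columns.get_loc("p_true")] = p_new
        truth.append(GenomicFeature(plant.chrom, plant.start, plant.end,
                                    f"dmr_truth_{i + 1:03d}", "DMR"))
    return MethylomeSample(sample_b.name, data, group=sample_b.group), truth


def choose_plant_regions(sample: MethylomeSample, context: str = "CA",
                         n_regions: int = 30, sites_per_region: int = 10,
                         max_span: int | None = None, min_separation: int = 5_000,
                         delta: float = 0.3) -> list[DmrPlant]:
    """Pick well-separated runs of consecutive context sites to plant DMRs in.

    The default span cap keeps every planted region above 3.5 cytosines per
    100 bp, so the truth regions satisfy the DMR density definition.
    """
    if max_span is None:
        max_span = int(sites_per_region * 100 / 3.5)
    plants: list[DmrPlant] = []
    for chrom in sample.chroms:
        tbl = sample.chrom_table(chrom)
        pos = tbl.loc[tbl["context"] == context, "pos"].to_numpy()
        last_end = -min_separation
        i = 0
        while i + sites_per_region <= len(pos) and len(plants) < n_regions:
            start, end = int(pos[i]), int(pos[i + sites_per_region - 1]) + 1
            if end - start <= max_span and start >= last_end + min_separation:
                plants.append(DmrPlant(chrom, start, end, context, delta))
                last_end = end
                i += sites_per_region
            else:
                i += 1
        if len(plants) >= n_regions:
            break
    return plants


def true_gene_mch(sample: MethylomeSample, genes: Sequence[GenomicFeature]) -> pd.Series:
    """Mean true CH methylation probability over each gene body (synthetic
    ground truth for the expression model)."""
    if "p_true" not in sample.data.columns:
        raise ValueError("sample lacks the synthetic p_true column")
    values = {}
    for gene in genes:
        tbl = sample.chrom_table(gene.chrom)
        pos = tbl["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [gene.start, gene.end])
        sub = tbl.iloc[lo:hi]
        sub = sub[sub["context"].isin(CH_SUBCONTEXTS)]
        if len(sub):
            values[gene.name] = float(sub["p_true"].mean())
    s = pd.Series(values, name="mch")
    s.index.name = "gene"
    return s


def simulate_expression(gene_mch: pd.Series, model: ExpressionModel,
                        seed: int) -> pd.Series:
    """Draw TPM values anticorrelated with gene-body mCH.

    log(TPM + 1) = a + b * mCH + Normal(0, sd), then TPM clipped at 0.
    Genes with missing mCH are omitted with a warning.
    """
    if model.b > 0:
        raise ValueError("expression model slope b must be <= 0")
    mch = gene_mch.dropna()
    if len(mch) < len(gene_mch):
        import logging
        logging.getLogger(__name__).warning(
            "omitting %d genes with missing mCH", len(gene_mch) - len(mch))
    rng = _rng(seed, "expression")
    log_tpm = model.a + model.b * mch.to_numpy()
    if model.sd > 0:
        log_tpm = log_tpm + rng.normal(0.0, model.sd, size=len(mch))
    tpm = np.maximum(np.expm1(log_tpm), 0.0)
    out = pd.Series(tpm, index=mch.index, name="tpm")
    out.index.name = "gene"
    return out
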
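"""Methylation-expression integration.

Sliding-window visualisation of the gene-body mCH vs expression
anticorrelation, cortical-enhancer CG delta analysis, and the per-gene
max-normalised transcription-factor panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylomeSample, NonconversionRates, aggregate_by_feature
from .io import GenomicFeature


@dataclass
class WindowProfile:
    """20-gene sliding-window means plus the unwindowed rank correlation."""

    windows: pd.DataFrame      # columns mch_mean, log_expr_mean
    rho: float                 # Spearman rho of unwindowed (mCH, TPM) pairs
    rho_p: float
    n_genes: int
    fit_slope: float           # linear fit on the windowed means
    fit_intercept: float


def sliding_window_profile(gene_mch: pd.Series, expression: pd.Series,
                           window: int = 20) -> WindowProfile:
    """Window-averaged mCH along the expression ranking.

    Genes are ordered by descending TPM (ties broken by gene name for
    determinism); windows of ``window`` genes advance by one gene. The
    expression axis is log10(TPM + 1). The headline statistic is the
    Spearman rho of the unwindowed pairs; if either vector is constant the
    correlation is reported missing (NaN).
    """
    df = pd.DataFrame({"mch": gene_mch, "tpm": expression}).dropna()
    n = len(df)
    if n < window:
        raise ValueError(f"need >= {window} genes with both values, have {n}")
    # ties in TPM resolve by gene name, so the profile is order-independent
    df = df.loc[sorted(df.index)].sort_values("tpm", ascending=False,
                                              kind="mergesort")
    mch = df["mch"].to_numpy()
    log_expr = np.log10(df["tpm"].to_numpy() + 1.0)
    kernel = np.full(window, 1.0 / window)
    windows = pd.DataFrame({
        "mch_mean": np.convolve(mch, kernel, mode="valid"),
        "log_expr_mean": np.convolve(log_expr, kernel, mode="valid"),
    }, index=pd.RangeIndex(n - window + 1, name="window"))
    if np.ptp(mch) == 0 or np.ptp(df["tpm"].to_numpy()) == 0:
        rho, rho_p = float("nan"), float("nan")
    else:
        res = stats.spearmanr(mch, df["tpm"].to_numpy())
        rho, rho_p = float(res.statistic), float(res.pvalue)
    x = windows["log_expr_mean"].to_numpy()
    if len(windows) >= 2 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, windows["mch_mean"], 1)
    else:  # a single window or a degenerate axis supports no line
        slope, intercept = np.nan, np.nan
    return WindowProfile(windows, rho, rho_p, n, float(slope), float(intercept))


def enhancer_deltas(enhancers: Sequence[GenomicFeature],
                    sample_a: MethylomeSample, sample_b: MethylomeSample,
                    context: str = "CG",
                    nonconversion_a: NonconversionRates | None = None,
                    nonconversion_b: NonconversionRates | None = None,
                    flag_threshold: float = 0.5, min_calls: int = 20,
                    ) -> tuple[pd.DataFrame, float]:
    """Per-enhancer corrected levels, deltas, and the hypermethylated fraction.

    delta = level(sample_a) - level(sample_b); an enhancer is flagged when
    delta > ``flag_threshold``. Enhancers below ``min_calls`` in either
    sample are excluded from the denominator. Returns the table and the
    flagged fraction among covered enhancers.
    """
    agg_a = aggregate_by_feature(sample_a, enhancers, context,
                                 nonconversion_a, min_calls)
    agg_b = aggregate_by_feature(sample_b, enhancers, context,
                                 nonconversion_b, min_calls)
    df = pd.DataFrame({
        "enhancer": agg_a["name"], "chrom": agg_a["chrom"],
        "start": agg_a["start"], "end": agg_a["end"],
        "level_a": agg_a["corrected_level"], "level_b": agg_b["corrected_level"],
        "covered": ~(agg_a["missing"] | agg_b["missing"]),
    })
    df["delta"] = df["level_a"] - df["level_b"]
    df["hypermethylated"] = df["covered"] & (df["delta"] > flag_threshold)
    n_covered = int(df["covered"].sum())
    if n_covered == 0:
        raise ValueError("no enhancer covered in both samples")
    fraction = float(df["hypermethylated"].sum()) / n_covered
    return df, fraction


def tf_panel(genes: Sequence[str], expression_a: pd.Series, expression_b: pd.Series,
             mch_a: pd.Series, mch_b: pd.Series) -> pd.DataFrame:
    """Per-gene max-normalised expression and gene-body mCH panel.

    For each gene, expression and mCH are divided by the larger of the two
    samples' values, so the larger sample reads exactly 1. A pair whose
    maximum is 0 (or with a missing value) yields missing cells. Genes are
    ordered by descending mCH difference (sample A - sample B).
    """
    if not genes:
        raise ValueError("gene list is empty")
    rows = []
    for gene in genes:
        row: dict[str, object] = {"gene": gene}
        for label, (a, b) in (("expr", (expression_a, expression_b)),
                              ("mch", (mch_a, mch_b))):
            va = a.get(gene, np.nan)
            vb = b.get(gene, np.nan)
            top = np.nanmax([va, vb]) if not (pd.isna(va) and pd.isna(vb)) else np.nan
            if pd.isna(va) or pd.isna(vb) or not top > 0:
                row[f"{label}_a"], row[f"{label}_b"] = np.nan, np.nan
            else:
                row[f"{label}_a"], row[f"{label}_b"] = va / top, vb / top
            row[f"{label}_delta"] = (va - vb) if not (pd.isna(va) or pd.isna(vb)) else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["mch_delta", "gene"], ascending=[False, True],
                        kind="mergesort", na_position="last")
    return df.reset_index(drop=True)
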
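"""Readers and writers for the external file formats.

All coordinates are 0-based half-open in memory. File dialects convert at
the boundary: the per-cytosine report stores 1-based positions, BED is
already 0-based half-open.

Formats
-------
* Cytosine report: TSV ``chrom  pos(1-based)  strand  count_m  count_u  context``
  with context one of CG/CA/CC/CT (the CH super-context is never stored).
* BED3/BED6 feature files.
* GMT gene-set collections (``name  description  gene...``).
* Two-column expression tables (``gene  tpm``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

log = logging.getLogger(__name__)

#: valid stored sequence contexts; "CH" is the query-time union of CA/CC/CT
CONTEXTS = ("CG", "CA", "CC", "CT")
CH_SUBCONTEXTS = ("CA", "CC", "CT")

FEATURE_TYPES = (
    "gene", "exon", "intron", "intergenic", "CGI", "TSS_window", "enhancer",
    "bin", "DMR", "dev_DMR_fetal", "dev_DMR_adult",
)


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


class CytosineRecord(NamedTuple):
    """One strand-resolved cytosine with its basecall counts."""

    chrom: str
    pos: int          # 0-based position of the C on its strand
    strand: str       # "+" or "-"
    context: str      # CG, CA, CC or CT
    count_m: int      # methylated basecalls
    count_total: int  # total basecalls (>= count_m)


@dataclass(frozen=True)
class GenomicFeature:
    """A typed genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str
    feature_type: str = "gene"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_cytosine_report(path: str | Path) -> list[CytosineRecord]:
    """Parse a per-cytosine bisulfite count report.

    File positions are 1-based and converted to 0-based. Rows with zero
    total coverage are retained (they carry positions but no calls).
    """
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, m_s, u_s, context = fields
            if context not in CONTEXTS:
                raise ParseError(f"{path}:{lineno}: unknown context token {context!r}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                pos = int(pos_s)
                count_m = int(m_s)
                count_u = int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos < 1 or count_m < 0 or count_u < 0:
                raise ParseError(f"{path}:{lineno}: negative count or position < 1")
            records.append(
                CytosineRecord(chrom, pos - 1, strand, context, count_m, count_m + count_u)
            )
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records in the report dialect (positions back to 1-based)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.count_m}\t"
                f"{r.count_total - r.count_m}\t{r.context}\n"
            )


def read_bed(path: str | Path, feature_type: str = "gene") -> list[GenomicFeature]:
    """Read BED3+ intervals as features of one type.

    Missing names become ``chrom:start-end``; missing strand becomes ``.``.
    """
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            feats.append(GenomicFeature(chrom, start, end, name, feature_type, strand))
    return feats


def write_bed(features: Iterable[GenomicFeature], path: str | Path,
              score: float | None = None) -> None:
    """Write features as BED6 (score column 0 unless given)."""
    with open(path, "w") as fh:
        for f in features:
            s = 0 if score is None else score
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{s}\t{f.strand}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection.

    Duplicate genes within a set are dropped (order-preserving) with a
    warning; duplicate set names are an error.
    """
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT needs name, description and >= 1 gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in collection:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                log.warning("gene set %r: dropped %d duplicate genes",
                            name, len(genes) - len(unique))
            if not unique:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            collection[name] = unique
    return collection


def write_gmt(collection: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def read_expression(path: str | Path) -> pd.Series:
    """Read a two-column ``gene  tpm`` table (optional header) as a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "tpm"], comment="#")
    if len(df) and df.iloc[0, 0] == "gene":  # header row present
        df = df.iloc[1:]
    tpm = pd.to_numeric(df["tpm"], errors="raise").astype(float)
    tpm.index = df["gene"].astype(str)
    tpm.index.name = "gene"
    tpm.name = "tpm"
    if (tpm < 0).any() or not pd.Series(tpm).pipe(lambda s: s.map(pd.notna).all()):
        raise ParseError(f"{path}: TPM values must be finite and non-negative")
    return tpm


def write_expression(tpm: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttpm\n")
        for gene, value in tpm.items():
            fh.write(f"{gene}\t{value:.6g}\n")
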
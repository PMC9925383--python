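"""Coding-strand bias of stranded RNAPII ChIP-seq reads.

PCR amplification of ChIP libraries is biased toward the coding strand
where a transcription-blocking lesion sits on the template strand, so a
per-gene coding-strand read fraction above 0.5 flags lesion-stalled
RNAPII. "Coding" reads are reads whose alignment strand equals the
gene's annotated strand (orientation-corrected, since genes lie on both
genomic strands).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, GeneModel, ReadSet
from .metrics import LengthClasses
from .profiling import bin_gene_body


def coding_strand_fraction(reads: ReadSet, gene: GeneModel) -> float:
    """Fraction of gene-body reads on the coding strand; NaN if no reads."""
    mask = (reads.chrom == gene.chrom) & (reads.midpoints >= gene.start) & (
        reads.midpoints < gene.end
    )
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    coding = int((reads.strand[mask] == gene.strand).sum())
    return coding / n


def split_by_strand(reads: ReadSet, catalog: GeneCatalog, k: int = 3):
    """Bin coding- and template-strand reads separately (genes x k)."""
    import dataclasses

    def subset(mask):
        return dataclasses.replace(
            reads,
            chrom=reads.chrom[mask],
            start=reads.start[mask],
            end=reads.end[mask],
            strand=reads.strand[mask],
            library_size=max(int(mask.sum()), 1),
        )

    # per-gene orientation: assign reads to genes once per strand value
    fwd = reads.strand == "+"
    plus = bin_gene_body(subset(fwd), catalog, k=k)
    minus = bin_gene_body(subset(~fwd), catalog, k=k)
    strands = pd.Series({g.gene_id: g.strand for g in catalog})
    is_fwd = (strands.reindex(plus.index) == "+").to_numpy()[:, None]
    coding = pd.DataFrame(
        np.where(is_fwd, plus, minus), index=plus.index, columns=plus.columns
    )
    template = pd.DataFrame(
        np.where(is_fwd, minus, plus), index=plus.index, columns=plus.columns
    )
    return coding, template


def coding_fraction_per_gene(coding: pd.DataFrame, template: pd.DataFrame) -> pd.Series:
    """Per-gene coding fraction from stranded count matrices; NaN if empty."""
    c = coding.sum(axis=1)
    t = template.sum(axis=1)
    total = (c + t).replace(0, np.nan)
    return (c / total).rename("coding_fraction")


def strand_bias_by_position(
    coding: pd.DataFrame, template: pd.DataFrame, n_bins: int = 3
) -> pd.Series:
    """Pooled coding fraction per gene-body position (proportional thirds).

    Input matrices may have any k >= ``n_bins``; column j is assigned to
    position ``floor(j * n_bins / k)`` (transcriptional order) and reads
    pooled across genes, so k divisible by ``n_bins`` gives exact thirds.
    """
    k = coding.shape[1]
    if k < n_bins:
        raise ValueError(f"k={k} < {n_bins} positions")
    pos = np.arange(k) * n_bins // k
    out = {}
    for i in range(n_bins):
        sel = pos == i
        c = coding.iloc[:, sel].to_numpy().sum()
        t = template.iloc[:, sel].to_numpy().sum()
        out[f"third_{i + 1}" if n_bins == 3 else f"pos_{i + 1}"] = (
            c / (c + t) if (c + t) > 0 else np.nan
        )
    return pd.Series(out, name="coding_fraction")


def strand_bias_by_position_from_reads(
    reads: ReadSet, catalog: GeneCatalog, n_bins: int = 3
) -> pd.Series:
    coding, template = split_by_strand(reads, catalog, k=n_bins)
    return strand_bias_by_position(coding, template, n_bins=n_bins)


def strand_bias_by_length_class(
    coding: pd.DataFrame,
    template: pd.DataFrame,
    classes: LengthClasses,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-length-class coding fraction, pooled (default) or gene-averaged.

    Pooling sums reads within the class before taking the fraction,
    which avoids small-n per-gene noise; ``mode='mean'`` averages
    per-gene fractions and reports the s.e.m. instead.
    """
    c = coding.sum(axis=1)
    t = template.sum(axis=1)
    df = pd.DataFrame({"coding": c, "template": t, "class": classes.labels}).dropna()
    rows = []
    for cls, sub in df.groupby("class"):
        total = sub["coding"].sum() + sub["template"].sum()
        if mode == "pooled":
            frac = sub["coding"].sum() / total if total else np.nan
            se = (
                np.sqrt(frac * (1 - frac) / total) if total and 0 <= frac <= 1 else np.nan
            )
        elif mode == "mean":
            per_gene = sub["coding"] / (sub["coding"] + sub["template"]).replace(0, np.nan)
            frac, se = per_gene.mean(), per_gene.sem()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"class": cls, "fraction": frac, "se": se, "n_genes": len(sub)})
    return pd.DataFrame(rows).set_index("class")
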
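"""Elongation statistics: density change, travel ratio, length classes,
per-kb loss slope, exon-output metrics and high-transcriptional-stress
gene selection.

The per-bin percentage density change is 100 * old / adult on replicate-
mean densities. Bins 1 and k carry TSS pausing and TTS accumulation
signal, so the middle bins 2..k-1 ("elongation phase") are analyzed;
with k = 20 that is the classic 18-bin window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, ReadSet, count_reads, derive_region

log = logging.getLogger(__name__)

GROUP_FIXED_BOUNDS_KB = (10, 22, 30, 50, 70, 110)  # left-closed class edges


@dataclass
class DensityChange:
    """Per-gene per-bin old/adult percentages plus cross-gene summaries."""

    per_gene: pd.DataFrame  # genes x bins, percent; NaN where adult = 0
    bin_mean: pd.Series
    bin_sem: pd.Series


@dataclass
class LengthClasses:
    """A six-way partition of genes by length."""

    labels: pd.Series  # gene_id -> class index 0..5
    summary: pd.DataFrame  # per class: n, mean_kb, median_kb
    mode: str

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1


def density_change_percent(old_rpm: pd.DataFrame, adult_rpm: pd.DataFrame) -> DensityChange:
    """Percentage density change per gene per bin: 100 * old / adult.

    Inputs are replicate-mean density matrices aligned on genes and
    bins. Bins with zero adult density are masked (NaN) and logged.
    """
    if not old_rpm.index.equals(adult_rpm.index) or old_rpm.shape != adult_rpm.shape:
        raise ValueError("old and adult matrices must be aligned on genes and bins")
    adult = adult_rpm.to_numpy(dtype=float)
    old = old_rpm.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(adult > 0, 100.0 * old / adult, np.nan)
    n_masked = int(np.isnan(pct).sum())
    if n_masked:
        log.info("density_change_percent: masked %d bins with zero adult density", n_masked)
    per_gene = pd.DataFrame(pct, index=old_rpm.index, columns=old_rpm.columns)
    return DensityChange(
        per_gene=per_gene,
        bin_mean=per_gene.mean(axis=0, skipna=True),
        bin_sem=per_gene.sem(axis=0, skipna=True),
    )


def elongation_phase(values):
    """Drop the first and last bin (TSS/TTS bins) of a k-bin object.

    Works on 1-D arrays/Series (length k) and DataFrames (genes x k).
    Re-application shrinks the window further; it is not idempotent.
    """
    if isinstance(values, pd.DataFrame):
        if values.shape[1] < 3:
            raise ValueError("need k >= 3 bins")
        return values.iloc[:, 1:-1]
    values = values if isinstance(values, pd.Series) else np.asarray(values)
    if len(values) < 3:
        raise ValueError("need k >= 3 bins")
    return values[1:-1] if not isinstance(values, pd.Series) else values.iloc[1:-1]


def three_bin_aggregate(elongation_matrix: pd.DataFrame, n_out: int = 3) -> pd.DataFrame:
    """Sum consecutive elongation bins into ``n_out`` equal aggregates."""
    k = elongation_matrix.shape[1]
    if k % n_out:
        raise ValueError(f"{k} elongation bins do not split into {n_out} aggregates")
    step = k // n_out
    out = {}
    for i in range(n_out):
        out[f"agg_{i + 1}"] = elongation_matrix.iloc[:, i * step : (i + 1) * step].sum(axis=1)
    return pd.DataFrame(out)


def three_bin_heatmap(
    old_elong: pd.DataFrame,
    adult_elong: pd.DataFrame,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold changes over three 6-bin aggregates.

    The 18 elongation bins are summed six at a time per group, then
    log2(old/adult) taken per gene per aggregate. ``pseudocount``
    defaults to half the smallest nonzero aggregate across both groups.
    """
    old3 = three_bin_aggregate(old_elong)
    adult3 = three_bin_aggregate(adult_elong)
    if pseudocount is None:
        vals = np.concatenate([old3.to_numpy().ravel(), adult3.to_numpy().ravel()])
        nz = vals[vals > 0]
        pseudocount = 0.5 * nz.min() if len(nz) else 1.0
    return np.log2((old3 + pseudocount) / (adult3.values + pseudocount))


def travel_ratio(chip_reads: ReadSet, gene: GeneModel, w: int = 300) -> float:
    """RNAPII pausing index: density at TSS±w over the early gene body.

    Read density (reads/bp) in the TSS window divided by density in the
    1 kb of gene body starting 300 bp downstream of the TSS. Returns NaN
    when the denominator is zero.
    """
    tss = derive_region(gene, "tss_window", w=w)
    body = derive_region(gene, "post_tss_1kb_body")
    tss_bp = sum(e - s for _, s, e in tss)
    body_bp = sum(e - s for _, s, e in body)
    n_tss = count_reads(chip_reads, tss)
    n_body = count_reads(chip_reads, body)
    if n_body == 0 or body_bp == 0 or tss_bp == 0:
        return float("nan")
    return (n_tss / tss_bp) / (n_body / body_bp)


def length_classes(lengths_bp: pd.Series, mode: str = "quantile6") -> LengthClasses:
    """Partition genes into six length classes.

    ``fixed_bounds`` uses left-closed edges 10/22/30/50/70/110 kb
    (a 21,999 bp gene is class 0; a 22,000 bp gene class 1);
    ``quantile6`` makes six near-equal classes, appropriate for
    synthetic catalogs.
    """
    lengths_bp = lengths_bp.astype(float)
    if mode == "fixed_bounds":
        edges_bp = [b * 1000 for b in GROUP_FIXED_BOUNDS_KB] + [np.inf]
        labels = pd.Series(
            np.searchsorted(edges_bp, lengths_bp.to_numpy(), side="right") - 1,
            index=lengths_bp.index,
        )
        if (labels < 0).any():
            raise ValueError("genes below 10 kb cannot be length-classed")
    elif mode == "quantile6":
        labels = pd.qcut(lengths_bp.rank(method="first"), 6, labels=False).astype(int)
    else:
        raise ValueError(f"unknown length-class mode {mode!r}")
    rows = []
    for c in range(6):
        sel = lengths_bp[labels == c]
        rows.append(
            {
                "class": c,
                "n": len(sel),
                "mean_kb": sel.mean() / 1000 if len(sel) else np.nan,
                "median_kb": sel.median() / 1000 if len(sel) else np.nan,
            }
        )
    return LengthClasses(labels=labels, summary=pd.DataFrame(rows).set_index("class"), mode=mode)


def gene_body_decline_by_class(
    change: DensityChange, lengths_bp: pd.Series, classes: LengthClasses
) -> pd.DataFrame:
    """Per-class percentage transcriptional decline over the gene body.

    For each class, the cross-gene mean density-change curve over the
    elongation-phase bins is fit by OLS against the bin-midpoint offset
    (in kb, using the class mean length), and the decline is the fitted
    line's relative drop from TSS to TTS:
    ``100 * (1 - yhat(TTS) / yhat(TSS))``. Extrapolating the elongation
    trend to the gene ends removes the bias from the excluded terminal
    bins, so a linear survival curve of slope beta yields exactly
    ``100 * beta * L``.
    """
    per_gene = elongation_phase(change.per_gene)
    k = change.per_gene.shape[1]
    rel_mid = (np.arange(1, k - 1) + 0.5) / k  # elongation-bin midpoints, fraction of L
    rows = []
    for c in range(classes.n_classes):
        ids = classes.labels.index[classes.labels == c]
        ids = ids.intersection(per_gene.index)
        if len(ids) == 0:
            continue
        curve = per_gene.loc[ids].mean(axis=0, skipna=True).to_numpy()
        mean_len_kb = lengths_bp.loc[ids].mean() / 1000.0
        x = rel_mid * mean_len_kb
        ok = np.isfinite(curve)
        slope, intercept = np.polyfit(x[ok], curve[ok], 1)
        y0 = intercept
        yL = intercept + slope * mean_len_kb
        decline = 100.0 * (1.0 - yL / y0) if y0 else np.nan
        rows.append(
            {"class": c, "n": len(ids), "mean_length_kb": mean_len_kb, "decline_percent": decline}
        )
    return pd.DataFrame(rows).set_index("class")


def per_kb_loss_slope(class_summary: pd.DataFrame) -> tuple[float, float]:
    """OLS slope of percentage decline versus mean class length (%/kb).

    ``class_summary`` needs columns ``mean_length_kb`` and
    ``decline_percent`` (>= 3 classes). Returns (slope, stderr).
    """
    import statsmodels.api as sm

    df = class_summary.dropna(subset=["mean_length_kb", "decline_percent"])
    if len(df) < 3:
        raise ValueError("need at least 3 length classes for the loss-slope regression")
    X = sm.add_constant(df["mean_length_kb"].to_numpy())
    fit = sm.OLS(df["decline_percent"].to_numpy(), X).fit()
    return float(fit.params[1]), float(fit.bse[1])


def first_last_exon_loss(
    exon_counts_by_group: dict[str, list[pd.DataFrame]],
    exon_lengths: pd.DataFrame,
) -> pd.DataFrame:
    """Aging fold of the last/first exon nascent-output ratio per gene.

    Per group, r = density(last exon) / density(first exon) on
    replicate-mean counts (densities in reads/bp — first and last exons
    differ in length). The aging loss fold is r(adult) / r(old); folds
    > 1 mean extra 5'->3' loss in old. Genes with zero first-exon or
    last-exon old density are masked.
    """
    r = {}
    for group, tables in exon_counts_by_group.items():
        mean = sum(t for t in tables) / len(tables)
        dens_first = mean["first_exon"] / exon_lengths["first_exon"]
        dens_last = mean["last_exon"] / exon_lengths["last_exon"]
        r[group] = (dens_last / dens_first.replace(0, np.nan)).rename(group)
    out = pd.DataFrame({"r_adult": r["adult"], "r_old": r["old"]})
    out["loss_fold"] = out["r_adult"] / out["r_old"].replace(0, np.nan)
    return out


def utr3_abundance(
    exon_counts_by_group: dict[str, list[pd.DataFrame]],
    exon_lengths: pd.DataFrame,
    classes: LengthClasses | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Relative full-transcript output from 3'UTR coverage: old / adult.

    Returns the per-gene ratio and, when ``classes`` is given, per-class
    means of the member genes.
    """
    dens = {}
    for group, tables in exon_counts_by_group.items():
        mean = sum(t for t in tables) / len(tables)
        ok = exon_lengths["utr3"] > 0
        if (~ok).any():
            log.warning("utr3_abundance: %d genes without 3'UTR skipped", int((~ok).sum()))
        dens[group] = (mean["utr3"] / exon_lengths["utr3"].where(ok)).rename(group)
    ratio = (dens["old"] / dens["adult"].replace(0, np.nan)).rename("utr3_old_over_adult")
    by_class = None
    if classes is not None:
        joined = pd.DataFrame({"ratio": ratio, "class": classes.labels}).dropna()
        by_class = joined.groupby("class")["ratio"].agg(["mean", "sem", "count"])
    return ratio, by_class


def select_ts_high(loss_folds: pd.Series, threshold: float = 1.5) -> set[str]:
    """Genes with strictly > ``threshold``-fold first-to-last exon loss."""
    folds = loss_folds.dropna()
    return set(folds.index[folds > threshold])
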
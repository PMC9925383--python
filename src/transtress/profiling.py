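"""Binned gene-body profiles: counting, normalization, background correction.

The central object is :class:`BinnedProfile` — one sample's genes × k
matrix of gene-body bin counts, where each gene body [TSS, TTS) is split
into k equal-width proportional bins in transcriptional orientation
(bin 1 at the TSS on both strands). Bin assignment uses exact rational
edges: a read midpoint at transcriptional offset ``x`` of a gene of
length ``L`` falls in bin ``floor(x * k / L)`` (clamped to k-1), which
avoids cumulative rounding when L is not divisible by k and makes the
bins an exact partition of the body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, ReadSet

log = logging.getLogger(__name__)


@dataclass
class BinnedProfile:
    """Genes × k bin-count (or density) matrix for one sample.

    ``data`` is a DataFrame indexed by gene_id with columns bin_1..bin_k.
    Raw counts are stored; convert with :func:`normalize_rpm`.
    """

    data: pd.DataFrame
    assay: str
    group: str
    replicate: int
    library_size: int
    sample_id: str = ""
    intergenic_reads: float = 0.0
    intergenic_bp: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("need k >= 3 bins")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if not self.sample_id:
            self.sample_id = f"{self.assay}_{self.group}_{self.replicate}"

    @property
    def k(self) -> int:
        return self.data.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    def rpm(self) -> pd.DataFrame:
        return normalize_rpm(self.data, self.library_size)


def bin_columns(k: int) -> list[str]:
    return [f"bin_{i}" for i in range(1, k + 1)]


def bin_gene_body(reads: ReadSet, catalog: GeneCatalog, k: int = 20) -> pd.DataFrame:
    """Assign read midpoints to k proportional gene-body bins.

    Returns an integer DataFrame (genes × k). Bin 1 is at the TSS for
    both strands. Raises if any gene is shorter than k (bins would be
    narrower than 1 bp).
    """
    if k < 3:
        raise ValueError("need k >= 3 bins")
    for g in catalog:
        if g.length < k:
            raise ValueError(f"gene {g.gene_id} shorter than k={k} bp; cannot bin")
    counts = np.zeros((len(catalog), k), dtype=np.int64)
    order = {g.gene_id: i for i, g in enumerate(catalog)}
    by_chrom: dict[str, list] = {}
    for g in catalog:
        by_chrom.setdefault(g.chrom, []).append(g)
    mids_all = reads.midpoints
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: g.start)
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        mask = reads.chrom == chrom
        if not mask.any():
            continue
        mids = mids_all[mask]
        gi = np.searchsorted(starts, mids, side="right") - 1
        ok = (gi >= 0) & (mids < ends[np.clip(gi, 0, len(genes) - 1)])
        for j, m in zip(gi[ok], mids[ok]):
            g = genes[j]
            off = g.offset_of(int(m))
            b = min(off * k // g.length, k - 1)
            counts[order[g.gene_id], b] += 1
    return pd.DataFrame(counts, index=pd.Index(catalog.gene_ids, name="gene_id"), columns=bin_columns(k))


def normalize_rpm(counts: pd.DataFrame | np.ndarray, library_size: float):
    """Reads-per-million scaling: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return counts * (1e6 / float(library_size))


def subtract_background(
    profile: BinnedProfile,
    catalog: GeneCatalog,
    intergenic_reads: float | None = None,
    intergenic_bp: float | None = None,
    input_profile: BinnedProfile | None = None,
) -> BinnedProfile:
    """Background-correct a profile's raw counts, flooring at zero.

    Two corrections, both in read units on raw counts (before RPM):
    the intra-sample step removes the intergenic read density (reads/bp)
    times each bin's width; the optional input-DNA step then removes the
    input profile's counts scaled to this sample's library size.
    """
    if intergenic_reads is None:
        intergenic_reads = profile.intergenic_reads
    if intergenic_bp is None:
        intergenic_bp = profile.intergenic_bp
    corrected = profile.data.astype(float).copy()
    if intergenic_reads:
        if not intergenic_bp or intergenic_bp <= 0:
            raise ValueError("intergenic_bp must be positive when intergenic reads are given")
        rate = intergenic_reads / intergenic_bp
        widths = pd.Series(
            {g.gene_id: g.length / profile.k for g in catalog}, name="width"
        ).reindex(corrected.index)
        corrected = corrected.sub(rate * widths, axis=0)
    if input_profile is not None:
        scale = profile.library_size / input_profile.library_size
        inp = input_profile.data.reindex(corrected.index).fillna(0.0) * scale
        corrected = corrected - inp.values
    corrected = corrected.clip(lower=0.0)
    return replace(profile, data=corrected)


def expressed_gene_set(
    profiles: list[BinnedProfile], min_rpm: float = 1.0
) -> set[str]:
    """Genes whose group-mean nascent-RNA profile has >= min_rpm in every bin.

    Evaluated on the replicate-mean RPM profile of each group, then
    intersected across groups so one expressed set serves both ages.
    """
    by_group: dict[str, list[pd.DataFrame]] = {}
    for p in profiles:
        by_group.setdefault(p.group, []).append(p.rpm())
    result: set[str] | None = None
    for group, mats in by_group.items():
        mean = sum(mats) / len(mats)
        ok = (mean >= min_rpm).all(axis=1)
        ids = set(mean.index[ok])
        result = ids if result is None else (result & ids)
    return result or set()


def group_mean_rpm(profiles: list[BinnedProfile], assay: str, group: str) -> pd.DataFrame:
    """Replicate-mean RPM matrix for one (assay, group)."""
    mats = [p.rpm() for p in profiles if p.assay == assay and p.group == group]
    if not mats:
        raise ValueError(f"no profiles for assay={assay!r} group={group!r}")
    return sum(mats) / len(mats)


def replicate_rpm(profiles: list[BinnedProfile], assay: str, group: str) -> list[pd.DataFrame]:
    mats = [
        p.rpm()
        for p in sorted(profiles, key=lambda p: p.replicate)
        if p.assay == assay and p.group == group
    ]
    if not mats:
        raise ValueError(f"no profiles for assay={assay!r} group={group!r}")
    return mats


def splice_site_profile(
    reads: ReadSet, catalog: GeneCatalog, halfwidth: int = 49
) -> pd.DataFrame:
    """Read-midpoint coverage around splice donor/acceptor sites.

    Offsets run [-halfwidth, +halfwidth] in transcriptional orientation
    (negative = upstream of the site). Donors are internal exon 3' ends,
    acceptors internal exon 5' starts. Single-exon genes are skipped with
    a warning. Returns a DataFrame indexed by offset with columns
    ``donor`` and ``acceptor``.
    """
    offsets = np.arange(-halfwidth, halfwidth + 1)
    out = pd.DataFrame(0, index=pd.Index(offsets, name="offset"), columns=["donor", "acceptor"])
    mids_all = reads.midpoints
    for g in catalog:
        if len(g.exons) < 2:
            log.warning("splice_site_profile: %s has <2 exons; skipped", g.gene_id)
            continue
        exons = list(g.exons) if g.strand == "+" else list(g.exons)[::-1]
        donors, acceptors = [], []
        for i, (s, e) in enumerate(exons):
            # transcriptional 3' end of the exon / 5' start of the exon
            d = e - 1 if g.strand == "+" else s
            a = s if g.strand == "+" else e - 1
            if i < len(exons) - 1:
                donors.append(d)
            if i > 0:
                acceptors.append(a)
        mask = reads.chrom == g.chrom
        if not mask.any():
            continue
        mids = mids_all[mask]
        sign = 1 if g.strand == "+" else -1
        for col, sites in (("donor", donors), ("acceptor", acceptors)):
            for site in sites:
                delta = sign * (mids - site)
                sel = np.abs(delta) <= halfwidth
                if sel.any():
                    vals, cnts = np.unique(delta[sel], return_counts=True)
                    out.loc[vals, col] += cnts
    return out
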
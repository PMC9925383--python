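"""Gene annotations, genomic regions and read records.

Coordinates are 0-based half-open (BED convention) throughout. A gene's
transcriptional offset of a genomic position ``p`` is ``p - start`` on the
'+' strand and ``end - 1 - p`` on the '-' strand, so that offset 0 is the
first transcribed base (TSS) in both orientations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

ASSAYS = ("EU", "ChIP_total", "ChIP_ser2p", "ChIP_ser5p", "input")
GROUPS = ("adult", "old")

REGION_KINDS = (
    "tss_window",
    "first_kb_from_tss",
    "first_kb_of_introns",
    "tss_to_20kb",
    "first_exon",
    "last_exon",
    "utr3",
    "gene_body",
    "post_tss_1kb_body",
)


class BedFormatError(ValueError):
    """Raised for malformed BED lines; message names the offending line."""


class RegionUnavailableError(ValueError):
    """Requested region kind needs annotation the gene does not carry."""


@dataclass(frozen=True)
class GeneModel:
    """A single collapsed gene model with exon structure.

    ``exons`` are (start, end) pairs in genomic order; ``utr3`` is an
    optional genomic interval contained in the transcriptionally last exon.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the TSS (as a point; the bound for '-')."""
        return self.start if self.strand == "+" else self.end

    def offset_of(self, position: int) -> int:
        """Transcriptional offset (bp from TSS) of a genomic position."""
        if self.strand == "+":
            return position - self.start
        return self.end - 1 - position

    def introns(self) -> list[tuple[int, int]]:
        """Intronic intervals in genomic order (empty without exons)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out


@dataclass
class GeneCatalog:
    """A set of gene models plus chromosome sizes."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in catalog")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length for g in self.genes}


@dataclass
class ReadSet:
    """Strand-annotated read intervals for one sample/assay.

    Coordinates are stored as parallel numpy arrays; ``library_size``
    defaults to the number of records but may be larger (total mapped
    reads of which these are the usable subset).
    """

    sample_id: str
    assay: str
    group: str
    replicate: int
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        n = len(self.start)
        if self.library_size == 0:
            self.library_size = n
        if self.library_size < n:
            raise ValueError("library_size must be >= number of records")
        if np.any(self.start >= self.end):
            raise ValueError("read records must satisfy start < end")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# BED parsing


def _split_bed_line(line: str) -> list[str]:
    return line.rstrip("\n").replace(",", ",").split()


def read_bed12(path, chrom_sizes: dict[str, int] | None = None) -> GeneCatalog:
    """Parse a BED12 file into a :class:`GeneCatalog`.

    Exons are reconstructed from blockSizes/blockStarts (relative to
    chromStart). The thickStart/thickEnd columns are ignored; an optional
    13th column ``utr3_start-utr3_end`` annotates the 3'UTR.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise BedFormatError(f"{path}:{lineno}: expected >=12 BED fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
                starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: malformed field ({exc})") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise BedFormatError(
                    f"{path}:{lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            utr3 = None
            if len(fields) >= 13 and "-" in fields[12]:
                a, b = fields[12].split("-")
                utr3 = (int(a), int(b))
            try:
                genes.append(
                    GeneModel(name, chrom, strand, start, end, exons=exons, utr3=utr3)
                )
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GeneCatalog(genes, chrom_sizes)


def read_bed6_reads(path, sample_meta: dict) -> ReadSet:
    """Parse a BED6 read file into a :class:`ReadSet`.

    ``sample_meta`` must provide sample_id/assay/group/replicate and may
    override ``library_size`` (default: number of records).
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise BedFormatError(f"{path}:{lineno}: BED6 requires 6 fields (strand missing?)")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise BedFormatError(
                    f"{path}:{lineno}: strand {strand!r} invalid; stranded reads are required"
                )
            try:
                starts.append(int(fields[1]))
                ends.append(int(fields[2]))
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: malformed coordinate ({exc})") from exc
            chroms.append(fields[0])
            strands.append(strand)
    return ReadSet(
        sample_id=sample_meta["sample_id"],
        assay=sample_meta["assay"],
        group=sample_meta["group"],
        replicate=int(sample_meta.get("replicate", 1)),
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        strand=np.asarray(strands, dtype="U1"),
        library_size=int(sample_meta.get("library_size", 0)),
    )


# ---------------------------------------------------------------------------
# Filtering and regions


def filter_unique_genes(catalog: GeneCatalog, min_length_bp: int = 10_000) -> GeneCatalog:
    """Keep genes that overlap no other gene and are >= ``min_length_bp``.

    Both members of an overlapping pair are removed, so only genes whose
    span is unique to themselves survive. Idempotent.
    """
    overlapping: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in catalog.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.end))
        for a, b in zip(glist, glist[1:]):
            if b.start < a.end:
                overlapping.add(a.gene_id)
                overlapping.add(b.gene_id)
        # sweep with running max end catches A..C overlaps hidden behind B
        max_end, max_gene = -1, None
        for g in glist:
            if max_gene is not None and g.start < max_end:
                overlapping.add(g.gene_id)
                overlapping.add(max_gene)
            if g.end > max_end:
                max_end, max_gene = g.end, g.gene_id
    kept = [
        g
        for g in catalog.genes
        if g.gene_id not in overlapping and g.length >= min_length_bp
    ]
    return GeneCatalog(kept, dict(catalog.chrom_sizes))


def _clip(intervals, lo, hi):
    out = []
    for chrom, s, e in intervals:
        s, e = max(s, lo), min(e, hi)
        if s < e:
            out.append((chrom, s, e))
    return out


def derive_region(
    gene: GeneModel,
    kind: str,
    w: int = 300,
    chrom_sizes: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Derive a named sub-region of a gene, in genomic coordinates.

    ``kind`` is one of :data:`REGION_KINDS`. "Downstream" means in
    transcriptional orientation, so on '-' genes regions extend toward
    lower coordinates. ``post_tss_1kb_body`` is the 1 kb of gene body
    starting 300 bp downstream of the TSS — the travel-ratio denominator.
    """
    if kind not in REGION_KINDS:
        raise ValueError(f"unknown region kind {kind!r}")
    c = gene.chrom
    fwd = gene.strand == "+"

    def from_tss(a: int, b: int) -> tuple[str, int, int]:
        # [a, b) bp downstream of the TSS, transcriptional orientation
        if fwd:
            return (c, gene.start + a, gene.start + b)
        return (c, gene.end - b, gene.end - a)

    if kind == "tss_window":
        region = [from_tss(-w, w)]
    elif kind == "first_kb_from_tss":
        region = [from_tss(0, 1000)]
    elif kind == "tss_to_20kb":
        region = [from_tss(0, min(20_000, gene.length))]
    elif kind == "gene_body":
        region = [(c, gene.start, gene.end)]
    elif kind == "post_tss_1kb_body":
        region = [from_tss(300, 1300)]
    elif kind == "first_kb_of_introns":
        introns = gene.introns()
        if not introns:
            raise RegionUnavailableError(f"{gene.gene_id}: no introns annotated")
        if not fwd:
            introns = introns[::-1]
        region, need = [], 1000
        for s, e in introns:
            take = min(need, e - s)
            region.append((c, s, s + take) if fwd else (c, e - take, e))
            need -= take
            if need == 0:
                break
    elif kind in ("first_exon", "last_exon"):
        if not gene.exons:
            raise RegionUnavailableError(f"{gene.gene_id}: no exons annotated")
        first = kind == "first_exon"
        ex = gene.exons[0 if first == fwd else -1]
        region = [(c, ex[0], ex[1])]
    elif kind == "utr3":
        if gene.utr3 is None:
            raise RegionUnavailableError(f"{gene.gene_id}: no 3'UTR annotated")
        region = [(c, gene.utr3[0], gene.utr3[1])]

    if chrom_sizes and c in chrom_sizes:
        region = _clip(region, 0, chrom_sizes[c])
    else:
        region = _clip(region, 0, float("inf"))
    return region


def count_reads(reads: ReadSet, intervals, mode: str = "midpoint") -> int:
    """Count reads falling in the union of ``intervals``.

    ``midpoint`` (default) counts a read if its midpoint lies in the
    union — every read counts at most once, so counts over a partition sum
    to the count over the whole. ``any_overlap`` counts any base overlap.
    """
    if mode not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if len(reads) == 0 or not intervals:
        return 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    total = 0
    mids = reads.midpoints
    for chrom, ivs in by_chrom.items():
        mask = reads.chrom == chrom
        if not mask.any():
            continue
        ivs = _merge(ivs)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        if mode == "midpoint":
            pos = mids[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ivs) - 1)])
            total += int(ok.sum())
        else:
            rs, re = reads.start[mask], reads.end[mask]
            hit = np.zeros(len(rs), dtype=bool)
            for s, e in ivs:
                hit |= (rs < e) & (re > s)
            total += int(hit.sum())
    return total


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def mirror_gene(gene: GeneModel) -> GeneModel:
    """Reflect a gene around its own span and flip its strand.

    Utility for the strand-mirror property: deriving a region on a '-'
    gene equals deriving on the reflected '+' gene and reflecting back.
    """
    pivot = gene.start + gene.end  # reflection: p -> pivot - 1 - p for points
    refl = lambda s, e: (pivot - e, pivot - s)  # noqa: E731 - interval reflection
    exons = tuple(sorted(refl(s, e) for s, e in gene.exons))
    utr3 = refl(*gene.utr3) if gene.utr3 else None
    return replace(
        gene,
        strand="+" if gene.strand == "-" else "-",
        exons=exons,
        utr3=utr3,
    )
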
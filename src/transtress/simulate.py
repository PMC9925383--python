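"""Synthetic adult/old EU-seq and RNAPII ChIP-seq data generator.

The generator emulates the statistical structure of nascent-RNA and
RNAPII occupancy sequencing from adult versus aged liver:

* per-gene expression rates (log-normal),
* an age-independent 5'->3' decline of nascent-RNA density along gene
  bodies (linear survival, ``1 - a*x`` with x in kb),
* an old-specific excess loss per kilobase (``1 - beta*x``), the
  gradual loss of productive transcription,
* excess RNAPII occupancy in old gene bodies from stalled and queued
  complexes — either *phenomenological* (a planted occupancy excess) or
  *mechanistic* (Poisson-placed template-strand lesions, each carrying
  one stalled plus ``queue_size`` queued complexes),
* coding-strand read bias at stalled sites (template-strand fragments
  fail to amplify with probability ``template_dropout``),
* replicate-level Poisson count noise and intergenic background reads.

Library sizes model total sequencing depth, which in these assays is
dominated by background/non-unique reads; gene-level signal shifts
therefore do not materially renormalize RPM, as in the real libraries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneCatalog, GeneModel, ReadSet
from .profiling import BinnedProfile, bin_columns

EXON_REGIONS = ("first_exon", "last_exon", "utr3")


@dataclass
class SimConfig:
    """All knobs of the synthetic adult/old liver dataset.

    Rates are per base pair unless the name says otherwise; percentages
    are in percent units. A fixed seed makes every output byte-identical.
    """

    seed: int = 0
    n_genes: int = 600
    length_range_kb: tuple[float, float] = (10.0, 300.0)
    n_replicates: int = 3
    expression_median: float = 0.01  # adult reads/bp at the TSS
    expression_sigma: float = 0.8  # log-normal sigma of per-gene rates
    adult_decline_per_kb: float = 0.30  # age-independent decline, %/kb
    old_excess_loss_per_kb: float = 0.35  # old-specific excess loss, %/kb
    lesion_density_per_100kb_diploid: float = 1.6
    queue_size: int = 3  # trailing complexes per lesion
    stalling_target_percent: float = 40.0  # mean gene-body occupancy excess
    stalling_length_exponent: float = 0.0  # >0 couples the excess to length
    template_dropout: float = 0.5  # P(template fragment at a lesion drops out)
    intergenic_rate: float = 1e-4  # background reads/bp
    chip_scale: float = 1.0  # ChIP reads per unit nascent density
    library_size: int = 20_000_000  # total mapped reads per sample
    k: int = 20  # gene-body bins
    overdispersion: float = 0.0  # gamma-Poisson dispersion; 0 = pure Poisson
    mode: str = "phenomenological"  # or "mechanistic"

    def __post_init__(self) -> None:
        if self.mode not in ("phenomenological", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in (
            "expression_median",
            "adult_decline_per_kb",
            "old_excess_loss_per_kb",
            "lesion_density_per_100kb_diploid",
            "stalling_target_percent",
            "intergenic_rate",
            "template_dropout",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.template_dropout <= 1:
            raise ValueError("template_dropout must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range_kb"] = list(self.length_range_kb)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "length_range_kb" in d:
            d["length_range_kb"] = tuple(d["length_range_kb"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class LesionMap:
    """Per-gene sorted template-strand lesion offsets (bp from the TSS)."""

    offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def count(self, gene_id: str) -> int:
        return len(self.offsets.get(gene_id, ()))

    def total(self) -> int:
        return sum(len(v) for v in self.offsets.values())


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, plus its ground truth."""

    config: SimConfig
    catalog: GeneCatalog
    profiles: list[BinnedProfile]
    strand_counts: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # sample -> (coding, template)
    exon_counts: dict[str, pd.DataFrame]  # EU sample -> gene x region counts
    exon_lengths: pd.DataFrame  # gene x region lengths (bp)
    lesions: LesionMap
    expression: pd.Series
    ground_truth: dict

    def eu_profiles(self) -> list[BinnedProfile]:
        return [p for p in self.profiles if p.assay == "EU"]

    def chip_profiles(self) -> list[BinnedProfile]:
        return [p for p in self.profiles if p.assay == "ChIP_total"]


# ---------------------------------------------------------------------------
# Catalog


def simulate_catalog(config: SimConfig, rng: np.random.Generator) -> GeneCatalog:
    """Non-overlapping genes with exon/UTR structure on synthetic chromosomes.

    Lengths are log-uniform over ``length_range_kb``; strands uniform;
    every gene has a first exon at the TSS and a last exon ending at the
    TTS whose transcriptional 3' part is the 3'UTR. Genes are separated
    by >= 20 kb gaps.
    """
    lo, hi = (x * 1000 for x in config.length_range_kb)
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes)).astype(int)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    capacity, gap = 120_000_000, 20_000
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    chrom_i, pos = 1, 50_000
    for i, (L, strand) in enumerate(zip(lengths, strands)):
        if pos + L + gap > capacity:
            chrom_sizes[f"chrS{chrom_i}"] = pos + gap
            chrom_i, pos = chrom_i + 1, 50_000
        chrom = f"chrS{chrom_i}"
        start, end = pos, pos + int(L)
        f_len = int(rng.integers(150, 400))
        l_len = int(rng.integers(600, 2500))
        if strand == "+":
            first = (start, start + f_len)
            last = (end - l_len, end)
            utr_len = int(0.6 * l_len)
            utr3 = (end - utr_len, end)
        else:
            first = (end - f_len, end)
            last = (start, start + l_len)
            utr_len = int(0.6 * l_len)
            utr3 = (start, start + utr_len)
        lo_int = min(first[0], last[0]) + max(f_len, l_len) + 500
        hi_int = max(first[1], last[1]) - max(f_len, l_len) - 700
        m = max(0, int(round(L / 30_000)))
        internal: list[tuple[int, int]] = []
        if m > 0 and hi_int - lo_int > 600 * (m + 1):
            anchors = np.linspace(lo_int, hi_int, m + 2)[1:-1].astype(int)
            jitter = rng.integers(-100, 101, size=m)
            for a in np.sort(anchors + jitter):
                internal.append((int(a), int(a) + 150))
        exons = tuple(sorted([first, last] + internal))
        genes.append(
            GeneModel(f"g{i:04d}", chrom, strand, start, end, exons=exons, utr3=utr3)
        )
        pos = end + gap
        chrom_sizes[chrom] = pos
    return GeneCatalog(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# Lesions


def place_lesions(
    gene: GeneModel, density_per_100kb_diploid: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson lesion offsets on one representative template-strand allele.

    Lesions occur equally on coding and template strands, so half of the
    diploid total lands on template strands; one template allele carries
    a Poisson(density/2 * L/100kb) count, uniform along the gene.
    """
    if density_per_100kb_diploid < 0:
        raise ValueError("lesion density must be >= 0")
    mean = (density_per_100kb_diploid / 2.0) * gene.length / 100_000.0
    n = rng.poisson(mean)
    return np.sort(rng.integers(0, gene.length, size=n))


# ---------------------------------------------------------------------------
# Expected densities


def _survival_factor(x_kb: np.ndarray, config: SimConfig, group: str) -> np.ndarray:
    a = config.adult_decline_per_kb / 100.0
    f = np.clip(1.0 - a * x_kb, 0.0, None)
    if group == "old":
        b = config.old_excess_loss_per_kb / 100.0
        f = f * np.clip(1.0 - b * x_kb, 0.0, None)
    return f


def expected_eu_bins(
    gene: GeneModel, expression: float, config: SimConfig, group: str
) -> np.ndarray:
    """Expected EU reads per gene-body bin (length/k bp wide)."""
    k = config.k
    mid_kb = (np.arange(k) + 0.5) / k * gene.length / 1000.0
    width = gene.length / k
    return expression * width * _survival_factor(mid_kb, config, group)


def expected_region_reads(
    gene: GeneModel,
    expression: float,
    config: SimConfig,
    group: str,
    region_bp: float,
    offset_mid_bp: float,
) -> float:
    """Expected reads in a sub-region from the same positional density."""
    f = _survival_factor(np.array([offset_mid_bp / 1000.0]), config, group)[0]
    return expression * region_bp * f


def simulate_eu_profile(
    gene: GeneModel,
    expression: float,
    config: SimConfig,
    group: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-bin EU density and Poisson counts per replicate.

    Returns ``(expected, counts)`` with counts of shape
    (n_replicates, k); the expectation includes intergenic background.
    """
    expected = expected_eu_bins(gene, expression, config, group)
    lam = expected + config.intergenic_rate * gene.length / config.k
    counts = _draw_counts(lam, config, rng, size=(config.n_replicates, config.k))
    return expected, counts


def _draw_counts(lam, config: SimConfig, rng: np.random.Generator, size=None):
    lam = np.broadcast_to(np.asarray(lam, dtype=float), size) if size else np.asarray(lam, float)
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = rng.gamma(shape, 1.0 / shape, size=lam.shape) * lam
    return rng.poisson(lam)


def calibrate_stalled_read_weight(
    productive_reads_total: float,
    n_lesions_total: float,
    config: SimConfig,
) -> float:
    """Reads contributed per stalled/queued complex so that retained
    stalled-fragment reads equal ``stalling_target_percent`` of
    productive gene-body reads, dataset-wide.

    Template dropout removes ``template_dropout/2`` of stalled
    fragments before sequencing; the calibration anticipates that.
    """
    complexes = n_lesions_total * (1 + config.queue_size)
    if complexes <= 0:
        return 0.0
    retained = 1.0 - config.template_dropout / 2.0
    return (config.stalling_target_percent / 100.0) * productive_reads_total / (
        complexes * retained
    )


def simulate_chip_profile(
    gene: GeneModel,
    expression: float,
    config: SimConfig,
    group: str,
    rng: np.random.Generator,
    lesions: np.ndarray | None = None,
    stall_weight: float = 0.0,
    stall_factor: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-bin expected and sampled RNAPII ChIP reads on both strands.

    Productive occupancy tracks the group's local nascent density. In
    phenomenological mode, old occupancy is productive * (1 + s) with
    ``s`` the planted gene excess (``stall_factor``). In mechanistic
    mode each lesion adds (1 + queue_size) complexes of ``stall_weight``
    reads at its bin; template-strand reads of those fragments drop out
    with probability ``template_dropout``. Productive reads split 50:50
    between coding and template strands.
    """
    k = config.k
    productive = config.chip_scale * expected_eu_bins(gene, expression, config, group)
    stalled = np.zeros(k)
    if group == "old":
        if config.mode == "phenomenological":
            s = config.stalling_target_percent / 100.0 if stall_factor is None else stall_factor
            stalled = productive * s
        elif lesions is not None and len(lesions) and stall_weight > 0:
            bins = np.minimum(lesions * k // gene.length, k - 1).astype(int)
            mass = stall_weight * (1 + config.queue_size)
            np.add.at(stalled, bins, mass)
    bg = config.intergenic_rate * gene.length / k
    drop = config.template_dropout if (group == "old" and config.mode == "mechanistic") else 0.0
    exp_coding = 0.5 * (productive + stalled) + bg / 2
    exp_template = 0.5 * productive + 0.5 * (1.0 - drop) * stalled + bg / 2
    shape = (config.n_replicates, k)
    coding = _draw_counts(exp_coding, config, rng, size=shape)
    template = _draw_counts(exp_template, config, rng, size=shape)
    return {
        "expected_total": exp_coding + exp_template - bg,
        "coding": coding,
        "template": template,
    }


# ---------------------------------------------------------------------------
# Whole-dataset simulation


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate the full adult/old x EU/ChIP replicate dataset."""
    rng = np.random.default_rng(config.seed)
    catalog = simulate_catalog(config, rng)
    gene_ids = catalog.gene_ids
    expression = pd.Series(
        config.expression_median
        * np.exp(rng.normal(0.0, config.expression_sigma, size=len(catalog))),
        index=gene_ids,
        name="expression",
    )
    lesions = LesionMap(
        {
            g.gene_id: place_lesions(g, config.lesion_density_per_100kb_diploid, rng)
            for g in catalog
        }
    )

    # planted per-gene occupancy excess (phenomenological mode)
    lengths = np.array([g.length for g in catalog], dtype=float)
    alpha = config.stalling_length_exponent
    weights = lengths**alpha
    s_gene = pd.Series(
        (config.stalling_target_percent / 100.0) * weights / weights.mean(),
        index=gene_ids,
        name="stall_factor",
    )

    # mechanistic calibration on expected old productive reads
    stall_weight = 0.0
    if config.mode == "mechanistic":
        prod_total = sum(
            config.chip_scale * expected_eu_bins(g, expression[g.gene_id], config, "old").sum()
            for g in catalog
        )
        stall_weight = calibrate_stalled_read_weight(prod_total, lesions.total(), config)

    total_gene_bp = float(lengths.sum())
    intergenic_bp = float(sum(catalog.chrom_sizes.values()) - total_gene_bp)

    profiles: list[BinnedProfile] = []
    strand_counts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    exon_counts: dict[str, pd.DataFrame] = {}
    cols = bin_columns(config.k)
    exon_len_rows = {}
    for g in catalog:
        f = g.exons[0] if g.strand == "+" else g.exons[-1]
        last = g.exons[-1] if g.strand == "+" else g.exons[0]
        exon_len_rows[g.gene_id] = {
            "first_exon": f[1] - f[0],
            "last_exon": last[1] - last[0],
            "utr3": (g.utr3[1] - g.utr3[0]) if g.utr3 else 0,
        }
    exon_lengths = pd.DataFrame.from_dict(exon_len_rows, orient="index")
    exon_lengths.index.name = "gene_id"

    def region_offsets(g: GeneModel) -> dict[str, float]:
        # transcriptional midpoint offsets of the three exon regions
        out = {}
        for name in EXON_REGIONS:
            if name == "first_exon":
                iv = g.exons[0] if g.strand == "+" else g.exons[-1]
            elif name == "last_exon":
                iv = g.exons[-1] if g.strand == "+" else g.exons[0]
            else:
                iv = g.utr3
            mid = (iv[0] + iv[1]) // 2
            out[name] = float(g.offset_of(mid))
        return out

    for group in ("adult", "old"):
        # EU
        eu_mats = [np.zeros((len(catalog), config.k), dtype=np.int64) for _ in range(config.n_replicates)]
        exon_mats = [np.zeros((len(catalog), len(EXON_REGIONS)), dtype=np.int64) for _ in range(config.n_replicates)]
        for gi, g in enumerate(catalog):
            E = expression[g.gene_id]
            _, counts = simulate_eu_profile(g, E, config, group, rng)
            offs = region_offsets(g)
            for r in range(config.n_replicates):
                eu_mats[r][gi] = counts[r]
            for ri, name in enumerate(EXON_REGIONS):
                bp = exon_len_rows[g.gene_id][name]
                lam = (
                    expected_region_reads(g, E, config, group, bp, offs[name])
                    + config.intergenic_rate * bp
                )
                draws = _draw_counts(lam, config, rng, size=(config.n_replicates, 1))
                for r in range(config.n_replicates):
                    exon_mats[r][gi, ri] = draws[r, 0]
        for r in range(config.n_replicates):
            sid = f"EU_{group}_{r + 1}"
            profiles.append(
                BinnedProfile(
                    data=pd.DataFrame(eu_mats[r], index=pd.Index(gene_ids, name="gene_id"), columns=cols),
                    assay="EU",
                    group=group,
                    replicate=r + 1,
                    library_size=config.library_size,
                    sample_id=sid,
                    intergenic_reads=float(rng.poisson(config.intergenic_rate * intergenic_bp)),
                    intergenic_bp=intergenic_bp,
                )
            )
            exon_counts[sid] = pd.DataFrame(
                exon_mats[r], index=pd.Index(gene_ids, name="gene_id"), columns=list(EXON_REGIONS)
            )
        # ChIP
        cod_mats = [np.zeros((len(catalog), config.k), dtype=np.int64) for _ in range(config.n_replicates)]
        tem_mats = [np.zeros((len(catalog), config.k), dtype=np.int64) for _ in range(config.n_replicates)]
        for gi, g in enumerate(catalog):
            res = simulate_chip_profile(
                g,
                expression[g.gene_id],
                config,
                group,
                rng,
                lesions=lesions.offsets.get(g.gene_id),
                stall_weight=stall_weight,
                stall_factor=s_gene[g.gene_id],
            )
            for r in range(config.n_replicates):
                cod_mats[r][gi] = res["coding"][r]
                tem_mats[r][gi] = res["template"][r]
        for r in range(config.n_replicates):
            sid = f"ChIP_{group}_{r + 1}"
            coding = pd.DataFrame(cod_mats[r], index=pd.Index(gene_ids, name="gene_id"), columns=cols)
            template = pd.DataFrame(tem_mats[r], index=pd.Index(gene_ids, name="gene_id"), columns=cols)
            profiles.append(
                BinnedProfile(
                    data=coding + template,
                    assay="ChIP_total",
                    group=group,
                    replicate=r + 1,
                    library_size=config.library_size,
                    sample_id=sid,
                    intergenic_reads=float(rng.poisson(config.intergenic_rate * intergenic_bp)),
                    intergenic_bp=intergenic_bp,
                )
            )
            strand_counts[sid] = (coding, template)

    ground_truth = {
        "adult_decline_per_kb": config.adult_decline_per_kb,
        "old_excess_loss_per_kb": config.old_excess_loss_per_kb,
        "stalling_target_percent": config.stalling_target_percent,
        "stall_factor_per_gene": s_gene.to_dict(),
        "stall_read_weight": stall_weight,
        "n_template_lesions": int(lesions.total()),
        "intergenic_bp": intergenic_bp,
    }
    return SimulatedDataset(
        config=config,
        catalog=catalog,
        profiles=profiles,
        strand_counts=strand_counts,
        exon_counts=exon_counts,
        exon_lengths=exon_lengths,
        lesions=lesions,
        expression=expression,
        ground_truth=ground_truth,
    )


def expected_nascent_fold(dataset: SimulatedDataset) -> float:
    """Adult/old fold of total expected gene-body nascent output.

    Sums the survival-model expectation over every gene and bin per
    group — the absolute transcriptional output ratio that per-library
    read-depth normalization would hide.
    """
    cfg = dataset.config
    adult = old = 0.0
    for g in dataset.catalog:
        E = dataset.expression[g.gene_id]
        adult += expected_eu_bins(g, E, cfg, "adult").sum()
        old += expected_eu_bins(g, E, cfg, "old").sum()
    return adult / old


# ---------------------------------------------------------------------------
# Read-level export (small-scale; used for round-trip checks and BED output)


def reads_from_bins(
    catalog: GeneCatalog,
    counts: pd.DataFrame,
    rng: np.random.Generator,
    sense: str = "gene",
    read_len: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Materialize read intervals whose midpoints reproduce ``counts``.

    ``sense`` is 'gene' (read strand = gene strand; EU and coding-strand
    ChIP reads) or 'anti' (template-strand reads). Binning the returned
    reads with the same k reproduces ``counts`` exactly.
    """
    k = counts.shape[1]
    chroms, starts, ends, strands = [], [], [], []
    for g in catalog:
        if g.gene_id not in counts.index:
            continue
        row = counts.loc[g.gene_id].to_numpy()
        L = g.length
        for b in range(k):
            n = int(row[b])
            if n == 0:
                continue
            off_lo = -((-b * L) // k)  # ceil(b*L/k)
            off_hi = -((-(b + 1) * L) // k) - 1
            offs = rng.integers(off_lo, off_hi + 1, size=n)
            pos = g.start + offs if g.strand == "+" else g.end - 1 - offs
            s = pos - read_len // 2
            chroms.extend([g.chrom] * n)
            starts.extend(s.tolist())
            ends.extend((s + read_len).tolist())
            if sense == "gene":
                strands.extend([g.strand] * n)
            else:
                strands.extend(["-" if g.strand == "+" else "+"] * n)
    return (
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(strands, dtype="U1"),
    )


def readset_from_bins(
    catalog: GeneCatalog,
    profile: BinnedProfile,
    rng: np.random.Generator,
    sense: str = "gene",
) -> ReadSet:
    c, s, e, st = reads_from_bins(catalog, profile.data, rng, sense=sense)
    return ReadSet(
        sample_id=profile.sample_id,
        assay=profile.assay,
        group=profile.group,
        replicate=profile.replicate,
        chrom=c,
        start=s,
        end=e,
        strand=st,
        library_size=max(profile.library_size, len(s)),
    )


# ---------------------------------------------------------------------------
# Disk round-trip


def write_dataset(
    dataset: SimulatedDataset, out_dir, force: bool = False, write_reads: bool = False
) -> Path:
    """Write BED12 catalog, per-sample count TSVs and a JSON manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    _write_bed12(dataset.catalog, out / "genes.bed")
    with open(out / "chrom.sizes", "w") as fh:
        for c, n in sorted(dataset.catalog.chrom_sizes.items()):
            fh.write(f"{c}\t{n}\n")
    samples = []
    for p in dataset.profiles:
        fname = f"{p.sample_id}.counts.tsv"
        p.data.to_csv(out / fname, sep="\t")
        entry = {
            "sample_id": p.sample_id,
            "assay": p.assay,
            "group": p.group,
            "replicate": p.replicate,
            "library_size": p.library_size,
            "intergenic_reads": p.intergenic_reads,
            "intergenic_bp": p.intergenic_bp,
            "counts": fname,
        }
        if p.sample_id in dataset.strand_counts:
            cod, tem = dataset.strand_counts[p.sample_id]
            cod.to_csv(out / f"{p.sample_id}.coding.tsv", sep="\t")
            tem.to_csv(out / f"{p.sample_id}.template.tsv", sep="\t")
            entry["coding"] = f"{p.sample_id}.coding.tsv"
            entry["template"] = f"{p.sample_id}.template.tsv"
        if p.sample_id in dataset.exon_counts:
            dataset.exon_counts[p.sample_id].to_csv(out / f"{p.sample_id}.exons.tsv", sep="\t")
            entry["exons"] = f"{p.sample_id}.exons.tsv"
        samples.append(entry)
    dataset.exon_lengths.to_csv(out / "exon_lengths.tsv", sep="\t")
    with open(out / "lesions.tsv", "w") as fh:
        fh.write("gene_id\toffsets\n")
        for gid in dataset.catalog.gene_ids:
            offs = dataset.lesions.offsets.get(gid, np.array([], dtype=int))
            fh.write(f"{gid}\t{','.join(map(str, offs.tolist()))}\n")
    if write_reads:
        rng = np.random.default_rng(dataset.config.seed + 10_000)
        for p in dataset.profiles:
            rs = readset_from_bins(dataset.catalog, p, rng)
            _write_bed6(rs, out / f"{p.sample_id}.reads.bed")
    manifest = {
        "config": dataset.config.to_dict(),
        "samples": samples,
        "ground_truth": dataset.ground_truth,
        "expression": dataset.expression.round(8).to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def read_dataset(in_dir) -> SimulatedDataset:
    """Load a dataset written by :func:`write_dataset`."""
    from .annotation import read_bed12

    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SimConfig.from_dict(manifest["config"])
    chrom_sizes = {}
    with open(src / "chrom.sizes") as fh:
        for line in fh:
            c, n = line.split()
            chrom_sizes[c] = int(n)
    catalog = read_bed12(src / "genes.bed", chrom_sizes=chrom_sizes)
    profiles, strand_counts, exon_counts = [], {}, {}
    for entry in manifest["samples"]:
        data = pd.read_csv(src / entry["counts"], sep="\t", index_col="gene_id")
        profiles.append(
            BinnedProfile(
                data=data,
                assay=entry["assay"],
                group=entry["group"],
                replicate=entry["replicate"],
                library_size=entry["library_size"],
                sample_id=entry["sample_id"],
                intergenic_reads=entry["intergenic_reads"],
                intergenic_bp=entry["intergenic_bp"],
            )
        )
        if "coding" in entry:
            strand_counts[entry["sample_id"]] = (
                pd.read_csv(src / entry["coding"], sep="\t", index_col="gene_id"),
                pd.read_csv(src / entry["template"], sep="\t", index_col="gene_id"),
            )
        if "exons" in entry:
            exon_counts[entry["sample_id"]] = pd.read_csv(
                src / entry["exons"], sep="\t", index_col="gene_id"
            )
    exon_lengths = pd.read_csv(src / "exon_lengths.tsv", sep="\t", index_col="gene_id")
    lesions = LesionMap()
    with open(src / "lesions.tsv") as fh:
        next(fh)
        for line in fh:
            gid, _, offs = line.rstrip("\n").partition("\t")
            lesions.offsets[gid] = (
                np.array([int(x) for x in offs.split(",")]) if offs else np.array([], dtype=int)
            )
    expression = pd.Series(manifest["expression"], name="expression")
    return SimulatedDataset(
        config=config,
        catalog=catalog,
        profiles=profiles,
        strand_counts=strand_counts,
        exon_counts=exon_counts,
        exon_lengths=exon_lengths,
        lesions=lesions,
        expression=expression,
        ground_truth=manifest["ground_truth"],
    )


def _write_bed12(catalog: GeneCatalog, path) -> None:
    with open(path, "w") as fh:
        for g in catalog:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            utr = f"\t{g.utr3[0]}-{g.utr3[1]}" if g.utr3 else ""
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}{utr}\n"
            )


def _write_bed6(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for c, s, e, st in zip(reads.chrom, reads.start, reads.end, reads.strand):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")


# ---------------------------------------------------------------------------
# Planted archetypes for the gene-group classifier


def simulate_archetype_features(
    n_per_group: int = 100,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Three-bin log2 fold-change features from four planted gene groups.

    Archetypes mirror the four biological patterns (promoter-up,
    promoter-down, steep-loss/steep-gain, remainder); effect sizes are
    several noise s.d. apart. Steep-loss genes are drawn longer. Returns
    (features, true_labels, gene_lengths_bp).
    """
    rng = rng or np.random.default_rng(0)
    archetypes = {
        "promoter_up": np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5]),
        "promoter_down": -np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5]),
        "glpt_high": np.array([0.0, -0.4, -0.8, 0.0, 0.4, 0.8]),
        "remainder": np.array([0.0, -0.05, -0.1, 0.0, 0.05, 0.1]),
    }
    rows, labels, lengths = [], [], []
    for name, center in archetypes.items():
        x = center + rng.normal(0.0, noise_sd, size=(n_per_group, 6))
        rows.append(x)
        labels.extend([name] * n_per_group)
        mean_len = 150_000 if name == "glpt_high" else 40_000
        lengths.extend(rng.integers(int(0.5 * mean_len), int(1.5 * mean_len), size=n_per_group).tolist())
    idx = pd.Index([f"g{i:04d}" for i in range(4 * n_per_group)], name="gene_id")
    cols = ["eu_bin1", "eu_bin2", "eu_bin3", "chip_bin1", "chip_bin2", "chip_bin3"]
    feats = pd.DataFrame(np.vstack(rows), index=idx, columns=cols)
    return feats, pd.Series(labels, index=idx, name="label"), pd.Series(lengths, index=idx, name="length")
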
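# Methods

## The analysis model

All coordinates are 0-based half-open (BED convention). A gene catalog
is reduced to genes that overlap no other gene (both members of every
overlapping pair are dropped, so each surviving span is unique to one
gene) and are at least 10 kb long — short genes concentrate too many
reads into too few bins for proportional gene-body analysis. Each gene
body [TSS, TTS) is split into k = 20 equal-width proportional bins in
transcriptional orientation; bin membership of a read midpoint at
offset x is `floor(x·k/L)` (clamped to k−1), which uses exact rational
edges and makes the bins a true partition: binned counts always sum to
the gene-body count. Midpoint assignment (rather than any-overlap) is
the default precisely so that this conservation holds.

Counts are corrected in read units before RPM conversion: first the
intra-sample intergenic background (intergenic reads per bp times bin
width) is removed, then, when input-DNA control profiles exist, the
library-scaled input counts; results are floored at zero because
negative densities are non-physical. The order of the two corrections
is a package choice — both are defined in read units, and applying them
before RPM keeps the arithmetic in one currency.

The expressed-gene universe is the set of genes whose *group-mean* EU
profile has at least 1 RPM in every bin, intersected across the two age
groups, so one gene set serves both ages. Group-mean (rather than
per-replicate) evaluation avoids membership churn from single noisy
replicates; this is a documented package choice.

### Elongation metrics

Per-bin density change is `100 × old/adult` on replicate-mean RPM; bins
with zero adult density are masked. The first and last bins carry TSS
pausing and TTS accumulation signal, so bins 2..k−1 (the "elongation
phase", 18 bins at k = 20) are analyzed. Three-bin summaries sum six
consecutive elongation bins and take per-gene log2 fold changes; zero
aggregates are protected by a pseudocount of half the smallest nonzero
aggregate (desk-scale matrices do contain zeros).

The per-kb loss slope is computed per length class: the cross-gene mean
density-change curve over the elongation bins is fit by OLS against the
bin-midpoint offset in kb (relative midpoints times the class mean
length), and the class decline is the fitted line's relative drop
evaluated from TSS to TTS, `100·(1 − ŷ(L)/ŷ(0))`. Extrapolating to the
gene ends matters: the elongation bins span only offsets 0.075L–0.925L,
and using the raw endpoint bins would systematically report ~0.85β for
a linear survival curve of true slope β. With the extrapolation, a pure
`1 − βx` curve yields exactly `100·β·L` per class, and the cross-class
OLS slope of decline versus mean class length recovers β. Length
classes are six quantile classes by default (appropriate for synthetic
catalogs); the fixed bounds 10/22/30/50/70/110 kb are available with
left-closed/right-open convention (the printed ranges overlap at their
endpoints, so a convention is required).

### Stalling

The estimator assumes the adult elongation-phase nascent output per
gene is proportional to adult elongation-phase RNAPII occupancy. The
baseline ratio r = ChIP/EU is taken on replicate-mean adult profiles;
the expected old occupancy is `EU_old · r` and

    stalling % = (observed − expected) / expected × 100

per gene on elongation-phase totals, each old ChIP replicate evaluated
against the mean baseline and then averaged. The division `EU_old /
EU_adult` is performed before multiplying by the adult ChIP total so a
self-comparison returns exactly 0%. The statistic is invariant under
joint library rescaling. Lesion arithmetic is linear: a density quoted
per 100 kb of diploid DNA over a gene set of total haploid span T gives
`T·d/100 kb · ploidy` expected lesions, half of them on template
strands; queued complexes per stalled RNAPII are
`round(stalled/lesions) − 1` with round-half-away-from-zero (the worked
numbers 18,000/4,480 → 4 per lesion → 3 queuing force that rounding).

### Strand bias

Reads are orientation-corrected per gene (coding = alignment strand
equals gene strand) before fractions are formed. Class and positional
summaries pool reads before dividing (per-gene fractions are noisy at
small read counts); per-gene averaging is available as an option.
Position summaries assign bin j of k to third `floor(j·3/k)`.

### EU incorporation model

EU incorporation along a nascent transcript is a Poisson process in
length with intensity λ (events per nt; mean spacing 1/λ); a transcript
of length L is captured iff at least one event occurs, P = 1 − e^(−λL).
Group summaries report median and IQR (the probability vectors are
non-Gaussian; a KS p-value against the fitted normal is reported), and
intensities a fixed fold apart are compared by a two-sided Mann–Whitney
U-test on the probability vectors. Note that on the saturated plateau
(λL ≫ 1) the *effect size* collapses while the rank test can remain
formally significant on deterministic vectors; the saturation property
worth asserting is the shrinking median gap, and the tests do so. λ is
a required user parameter; no default is assumed.

### Classification

Genes are clustered by k-means (n = 8 clusters, fixed seed, features
standardized, genes processed in sorted order so the partition is
input-order invariant) on the six-dimensional vector of three EU plus
three ChIP log2 fold-change aggregates. Clusters are mapped to four
biological groups by centroid rules: all-positive EU and ChIP →
promoter-upregulated; all-negative both → promoter-downregulated; EU
dropping and ChIP rising by at least δ from the first to the third
aggregate → steep progressive loss (GLPT-high); otherwise remainder.
δ = 0.26 log2 units (≈1.2-fold) separates "steep" from "mild"; it is a
configurable package constant, not an empirical estimate. Ties are
broken by rule priority (up > down > GLPT-high > remainder), logged.

## The synthetic-data generator

The generator emulates adult vs old liver sequencing at desk scale. Its
defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 600 | genes on synthetic chromosomes, ≥20 kb gaps |
| length_range_kb | (10, 300) | log-uniform gene lengths |
| n_replicates | 3 | biological replicates per age group |
| expression_median / sigma | 0.01 reads/bp, 0.8 | log-normal per-gene rates |
| adult_decline_per_kb | 0.30 % | age-independent 5'→3' decline |
| old_excess_loss_per_kb | 0.35 % | old-specific excess loss (β) |
| lesion_density_per_100kb_diploid | 1.6 | Poisson lesion intensity |
| queue_size | 3 | trailing complexes per lesion |
| stalling_target_percent | 40 | mean gene-body occupancy excess |
| template_dropout | 0.5 | P(template fragment at a lesion drops out) |
| intergenic_rate | 1e-4 reads/bp | background |
| library_size | 2×10⁷ | total mapped reads per sample |

Expected nascent density at offset x kb is `E_g·(1 − a·x)` for adult
and `E_g·(1 − a·x)(1 − β·x)` for old, floored at zero — the old excess
is linear, not exponential, because the loss is reported as a constant
per-kb rate. The adult rate a has no measured value and is an explicit
knob, not a claim. Counts are Poisson per bin per replicate (a
negative-binomial overdispersion knob exists, default off); exon-region
counts (first exon, last exon, 3'UTR) derive from the same positional
density. ChIP occupancy tracks the group's local nascent density;
phenomenological old profiles are multiplied by (1 + s) with s the
planted excess (optionally length-coupled), while mechanistic mode
places Poisson(β_lesion·L/2·allele) lesions on one representative
template allele (half the diploid total lands on template strands; one
allele is modeled), adds (1 + queue_size) complexes of calibrated read
weight at each lesion's bin, and drops template-strand reads of those
fragments with probability `template_dropout`. The calibration sets the
per-complex read weight so that *retained* stalled-fragment reads equal
the target percentage of productive old reads dataset-wide.

Library sizes model total sequencing depth, which in these assays is
dominated by background and non-unique reads; gene-level signal shifts
therefore do not materially renormalize RPM. This is why the stalling
excess survives per-library normalization, as it does in the real
assays where gene-body reads are a small fraction of the library.

What the generator does not emulate: sequence content, fragment-length
and GC effects, PCR duplication, splicing kinetics, repair kinetics
over time, isoform structure beyond one model per gene, and the
empirical length-expression coupling of real liver (expression and
length are drawn independently). Passing tests on this generator
demonstrate the estimators' correctness and calibration under the
stated statistical structure, not performance on real libraries.

A note on absolute output: with lengths log-uniform on 10–300 kb and
independent expression, the closed-form adult/old fold of total
gene-body output is E[A]/E[O] ≈ 1.27 (A = L(1 − aL/2),
O = L − (a+β)L²/2 + aβL³/3). A larger fold (as in tissue, where long
genes dominate the nascent pool more strongly) requires a
longer-weighted catalog; the generator reports what its stated
conditions produce.

## Problem sizes and numerical choices

Analyses and tests run at 600 genes × 3 replicates × 2 assays × 2
groups, k = 20; the loss-slope estimate is averaged over ten seeds.
Zero-denominator cells (adult bins, first-exon densities, expected
occupancies) are masked as NaN and logged rather than imputed. RPM uses
the sample's library size; background subtraction precedes RPM. All
randomness flows through `numpy.random.Generator` seeded from
`SimConfig.seed`; identical configurations produce byte-identical
written datasets.

## Known limitations

- Per-gene density-change ratios are ratio-of-means estimates; at very
  low adult bin counts they are upward-biased (Jensen), which the ≥1
  RPM expression filter bounds but does not remove.
- The four-group classifier encodes the printed group descriptions as
  centroid rules; the original clustering criteria beyond those
  descriptions are not reproducible, and real group sizes are
  data-dependent (a non-goal).
- The stalling estimator attributes *all* EU/ChIP discordance to
  nonproductive occupancy; systematic assay efficiency differences
  between ages would alias into it. The generator has no such term.
- Travel ratios and splice-site profiles operate on read-level input
  and are exercised on small read sets; the binned pipeline does not
  recompute them from matrices.
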
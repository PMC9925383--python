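# transtress

Transcriptional-stress analysis of nascent-RNA sequencing (EU-seq) and
RNA-polymerase-II ChIP-seq gene-body profiles in aging tissue.

Aged liver shows a paradox: nascent RNA synthesis drops ~1.5-fold while
elongating RNAPII *increases*. The resolution is gene-length-dependent
loss of productive elongation: nascent-RNA density declines ~0.35% per
kilobase of distance transcribed in old tissue, while RNAPII piles up in
gene bodies — polymerases stalled on transcription-blocking DNA lesions
(plus the complexes queuing behind them) occupy genes without producing
RNA. This package implements the quantitative toolkit for that analysis
and a synthetic-data generator that emulates the adult-vs-old sequencing
structure, so every stage runs without any external download.

## What it computes

For genes split into k = 20 proportional gene-body bins (bin 1 at the
TSS; the middle bins 2–19 are the elongation phase):

- **Density change** per bin: `100 × old / adult` on replicate-mean RPM,
  with per-bin t-tests; **3-bin log2 fold-change** matrices for
  clustering; four biological gene groups (promoter-up/-down, steep
  progressive loss "GLPT-high", remainder) from k-means on joint
  EU/ChIP features.
- **Excess loss per kb**: each of six gene-length classes gets a
  percentage decline over the gene body (elongation-phase trend
  extrapolated TSS→TTS); the OLS slope of decline versus mean class
  length is the per-kb loss rate (β, in %/kb).
- **RNAPII stalling**: with the adult baseline ratio
  r = ChIP/EU on elongation-phase totals,
  `stalling % = (observed − r·EU_old) / (r·EU_old) × 100`.
- **Lesion arithmetic**: expected transcription-blocking lesions from a
  density per 100 kb (1.6/100 kb diploid ≈ 2 J m⁻² UVC), template-strand
  half, and queued complexes per stalled RNAPII.
- **Coding-strand bias**: orientation-corrected coding-strand read
  fractions per gene, by gene-body third and by length class — the
  PCR-level signature of template-strand lesions.
- **EU incorporation model**: capture probability
  `P = 1 − exp(−λL)` for a Poisson process in transcript length, with
  median/IQR summaries and Mann–Whitney comparison of 1.5-fold-apart
  intensities.

The generator has a *phenomenological* mode (planted per-kb loss and
occupancy excess) and a *mechanistic* mode (Poisson lesions on template
strands, 1 + queue_size complexes per lesion, template-strand fragment
dropout at lesion sites).

## Worked example

```python
from transtress import SimConfig, TranscriptionalStressModel

model = TranscriptionalStressModel.from_simulation(SimConfig(seed=1))
results = model.fit(seed=1)
print(results.summary())
```

```
Transcriptional stress analysis (old vs adult)
======================================================
expressed genes (>=1 RPM all bins, both ages) : 164
gene-body nascent-output fold (adult / old)   : 1.253
excess loss slope (% per kb)                  : 0.355 +/- 0.018
nonproductive RNAPII in gene bodies (%)       : 39.3 (s.d. 4.9, n=164)
gene groups: promoter_up=0, promoter_down=0, glpt_high=0, remainder=164
TS-high genes (>1.5-fold exon loss)           : 70
coding-strand fraction (old ChIP, by third)   : 0.500, 0.500, 0.499
------------------------------------------------------
per-class decline:
        n  mean_length_kb  decline_percent
class
0      28           29.60            10.98
1      27           44.68            11.78
2      27           64.33            24.07
3      27           90.01            30.53
4      27          122.95            43.75
5      28          173.69            60.27
```

Reading this: 164 of 600 simulated genes pass the ≥1-RPM-per-bin
expression filter in both ages; the slope of per-class decline versus
mean length recovers the planted 0.35 %/kb excess loss; the stalling
estimator recovers the planted 40% nonproductive RNAPII; the
coding-strand fraction stays at 0.5 because the default mode plants no
lesions (run `SimConfig(mode="mechanistic")` to see the bias emerge and
rise toward gene ends). The same pipeline runs from the shell:

```bash
transtress simulate --out data/ --seed 1
transtress run --dataset data/ --seed 1 --out report/
transtress lesions --total-bp 280010046 --density 1.6 --stalled 18000
```

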
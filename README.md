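# seedarray

Dual-platform microarray analysis of *Arabidopsis thaliana* silique
transcriptomes from interploidy crosses and FIS-class mutants.

## The scientific problem

Crossing plants of different ploidies unbalances the maternal:paternal
genome ratio in the endosperm. Paternal excess (2xX4x, 2xX6x crosses)
drives endosperm overproliferation and larger seeds; maternal excess
(4xX2x, 6xX2x) inhibits endosperm growth. Maternal mutations in
FIS-class Polycomb genes (*FIS1/MEA*, *MSI1*) phenocopy paternal excess
even at a normal genome ratio. Profiling siliques from these crosses on
two independent array platforms — Affymetrix ATH1 (one-color,
comparison statistics from MAS5/GCOS) and custom Agilent two-dye 60-mer
arrays with dye swaps — lets differential-expression calls be required
to replicate across platforms, and lets whole-sample expression
profiles be tested for a paternalized/maternalized dichotomy.

`seedarray` implements that analysis chain as a reusable library for
anyone working with two-platform expression designs:

- **pSLR weighting** — MAS5 pairwise comparisons yield a signal
  log2-ratio (SLR) and a change P-value per probe set (P near 0:
  confident increase; near 1: confident decrease). These are combined as

  `pSLR = SLR · w(p*)`, `p* = 2·min(P, 1−P)`,
  `w(p*) = 1 / (1 + exp((2p* − 1)/0.01))`

  so statistically unsupported log-ratios shrink to zero while confident
  ones keep their SLR. The four comparisons per two-replicate cross (two
  experimental × two control replicates; two for single-replicate
  *msi1*) are averaged.
- **Dye-swap averaging** — Agilent log2(experimental/control) ratios
  from the two swapped-dye arrays are averaged, cancelling dye bias.
- **Probe correspondence** — Affymetrix probe sets (≥ 9 of 11 exact PM
  25-mer hits) and 60-mer probes (best ungapped placement with identity
  Q = matches/60 ≥ 5/6, best sense match kept per transcript) are paired
  through shared transcripts or direct probe-to-target matches.
- **Calls and consensus** — up: value ≥ 0.6; down: ≤ −0.6; broader
  not_up (≤ 0.3) / not_down (≥ −0.3) flags; a consensus call requires
  both platforms.
- **Contrast sets** — conjunctive recipes over the call table (e.g.
  up in 2xX4x and 2xX6x, not up in 4xX2x and 6xX2x = genes strongly
  associated with endosperm overproliferation), plus agreement
  percentages (100 · overlap / min set size) and annotation fractions.
- **Sample clustering** — 50% variance filter, complete linkage under
  Pearson/covariance/cosine distances, PCA cross-check.
- **Enrichment** — two-sided Fisher exact tests against the annotated
  present-gene background with Benjamini–Hochberg correction.
- **qRT-PCR concordance** — Pfaffl efficiency-corrected ratios
  (E_t^ΔCTt / E_r^ΔCTr) called with the same ±0.6 log2 rule and scored
  against microarray calls per platform and cross.

A seeded synthetic-data module emulates the full study design — seven
crosses, replicate structure, platform-specific noise, dye bias,
low-expression genes, and planted seed-class truth — so the whole
pipeline is testable without downloading the original arrays (GEO
accession GSE20007).

## Worked example

```python
import seedarray as sa

cfg = sa.SimulationConfig(n_genes=500, seed=42)
truth = sa.generate_truth(cfg)
comparisons, detection = sa.generate_affymetrix(truth, cfg)
dyeswap = sa.generate_agilent(truth, cfg)

summary = sa.summarize_genes(comparisons, detection, dyeswap, truth.gene_map())
counts = sa.count_calls(sa.build_call_table(summary))
print(counts.to_string(index=False))
```

prints

```
  cross  affy_up agilent_up overlap_up  affy_down agilent_down overlap_down
  2xX4x       13         13         13         12           12           12
  2xX6x       13         13         13         12           12           12
  4xX2x       13         13         13         12           12           12
  6xX2x       13         13         13         12           12           12
fis1X2x       23         23         23         12           12           12
   msi1       23       <NA>       <NA>         12         <NA>         <NA>
```

The 500 genes include 25 planted large-seed genes (13 up-type, 12
down-type), 25 small-seed genes and 10 FIS-up genes; the counts show
the calls recovering exactly that structure (fis1X2x and msi1 gain the
10 FIS-up genes on top of the 13 class genes), with full agreement
between platforms at this noise level. msi1 has no Agilent arrays, so
its overlap cells are empty. The `examples/` directory holds one short
script per capability (simulation/calls, probe correspondence,
contrast sets, clustering, enrichment, qPCR concordance); each prints
its results and a line on what they mean. A thin CLI mirrors the
stages: `seedarray simulate | map-probes | summarize | call | contrast
| cluster | enrich | qpcr | run`.

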
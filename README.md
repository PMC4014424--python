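# nrpeak

Analysis toolkit for genome-wide binding of non-steroidal nuclear receptors
(the motivating case is the orphan receptor TR4/NR2C2 in differentiating
human erythroid cells), integrating ChIP-seq peak calls with
shRNA-knockdown RNA-seq, repeat-element motif grammar, evolutionary
conservation and enhancer chromatin marks. It is written for computational
biologists who have peak calls, gene models, expression tables and interval
tracks in standard text formats and want the downstream regulatory-genomics
analysis as a tested, seeded, reusable library rather than a one-off script
stack.

## What it computes

**Peak annotation.** Each peak is assigned to the gene with the nearest
transcription start site (distance measured from the peak center) and
classified into mutually exclusive bands: promoter (−2 kb to −1 bp),
5′ distal I (−2 to −10 kb), 5′ distal II (−10 to −100 kb), within gene
(TSS→TES, resolved to exon/intron *k*), the mirrored 3′ bands past the TES,
and gene desert (>100 kb from every TSS and TES). A separate
proximal-promoter flag marks peaks within ±1 kb of the TSS.

**Repeat-element scanning.** Nuclear receptors bind paired hexameric
half-sites *h* ∈ {AGGTCA, AGTTCA, AGAACA} arranged as direct, inverted or
everted repeats with 0–8 spacer bases:

    DRn:  h1 · N^n · h2        IRn:  h1 · N^n · rc(h2)        ERn:  rc(h1) · N^n · h2

The scanner matches this grammar explicitly over 250-nt peak-center
windows with a configurable mismatch budget (default ≤1 per half-site, ≤2
total), assigns each peak one best element (fewest mismatches; ties break
DR < IR < ER, smaller spacer, leftmost, + strand), builds per-stratum
frequency tables and compares proximal-promoter against gene-distal peaks
with a two-proportion z-test.

**Knockdown integration.** A gene is differentially expressed under one
shRNA when (FPKM_kd + ε)/(FPKM_ctrl + ε) ≥ 2 or ≤ ½ (ε = 0.01) and either
FPKM reaches 0.1; genes responsive to both independent shRNAs form the
common set, split into induced/repressed after knockdown. The
promoter-bound gene cohort's log2 fold-change distribution is tested
against all expressed genes (Welch two-tailed t), and gene-distal peaks
are re-assigned to the nearest *differentially expressed* gene with
summary statistics (unique targets, median distance, induced fraction).

**Conservation.** Positional mean per-base conservation around peak
centers, per-peak means over fixed 250-nt windows (unscored bases count
0), and a null built from random same-chromosome intervals matched for
length and GC content (±0.02) that avoid all peak windows.

**Enhancer marks.** Counts of distal peaks whose ±2 kb flank intersects
P300 / H3K27ac / H3K4me1 / H3K27me3 intervals, per mark and in aggregate.

**Synthetic data.** A seeded generator produces a complete input bundle —
genome, gene models, peaks with planted region classes and motifs,
conservation bumps, planted knockdown responses, mark intervals — with a
ground-truth manifest, so every stage is testable end to end with no
downloads.

## Worked example

```python
from nrpeak import SimulationConfig, generate, annotate_peaks
from nrpeak.peak_annotation import proximal_promoter_summary

cfg = SimulationConfig(
    n_chromosomes=2, chromosome_length=1_200_000, genes_per_chromosome=12,
    gene_cluster=(60_000, 700_000), strata={"D8": 150}, n_extra_genes=100,
)
bundle = generate(cfg, seed=7)
cls = annotate_peaks(bundle.peaks_by_stratum["D8"], bundle.genes)
print(proximal_promoter_summary(cls))
```

prints

```
{'n_proximal_promoter': 37, 'n_total': 150, 'percent': 25}
```

— 37 of the 150 generated peaks sit within ±1 kb of their assigned TSS
(25%), matching the generator's planted promoter-proximal placement bias.
The scripts in `examples/` walk through each capability the same way
(generation + truth verification, annotation, motif scanning, knockdown
integration, conservation, enhancer marks, and the full pipeline); each
prints the numbers it computes and what they mean. A thin CLI (`nrpeak
simulate|annotate|run|convert|validate`) wraps the same functions for
shell use.

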
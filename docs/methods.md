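# Methods

This note documents the models, conventions and design choices behind
`nrpeak`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Coordinates and formats

All intervals are 0-based half-open internally (the BED convention).
Readers perform every dialect conversion at the boundary: refFlat and
BED12 are already 0-based; wiggle `fixedStep` starts are 1-based and
shifted on read. An even-width interval has no exact center; we define
`center = start + floor(width/2)`, which is deterministic and matches BED
integer arithmetic. Conservation tracks are sparse maps position→score
with scores validated into [0, 1]; positions absent from the track score
0, the convention for unscored bases in per-base conservation tracks, so
per-peak means use a fixed denominator (the window length) rather than
the covered-base count.

## Peak annotation

Assignment minimizes |peak center − TSS| over all gene models on the
peak's chromosome. Ties break by smaller |center − TES|, then
lexicographic gene id — deterministic and data-independent. Signed
distances are oriented by the assigned gene's strand: negative means
upstream of the TSS in the gene's reading direction.

Band edges are not fully determined by prose descriptions like "promoter
from −0.001 to −2 kb"; we fix them so the classes tile the integers
exactly: promoter [−2000, −1], 5′ distal I (−10000, −2000), 5′ distal II
[−100000, −10000], with mirrored bands measured from the TES on the 3′
side, `within_gene` for centers in [tx_start, tx_end), and gene desert
when both |TSS distance| and |TES distance| exceed 100 kb. A peak
centered exactly on the TSS is `within_gene` (the promoter band starts
strictly upstream). The proximal-promoter flag (|d| ≤ 1 kb) is orthogonal
to the class taxonomy because promoter-centered summaries use ±1 kb while
the class taxonomy uses the 2-kb promoter band; for gene models shorter
than 1 kb the flag can in principle coincide with a 3′ class, which the
generator's ≥5-kb genes avoid. Exon/intron indices are 1-based and
counted 5′→3′ in the gene's orientation.

Percentages everywhere are integer round-half-away-from-zero, matching
how such tables are conventionally printed, and are always reported with
their numerator and denominator.

## Repeat-element grammar scanner

The scanner is an explicit consensus-with-mismatch implementation of the
nuclear-receptor repeat grammar rather than a hidden-Markov half-site
model: deterministic, exhaustively enumerable, and therefore verifiable
against a brute-force oracle. Half-sites are AGGTCA/AGTTCA/AGAACA on
equal footing (a flag restricts to AG(G/T)TCA); each half independently
takes its minimal Hamming distance over the consensus set; an element is
called when each half is within `max_mismatch_per_half` (default 1) and
the total is within `max_total_mismatch` (default 2). A literal `N`
anywhere in the footprint disqualifies the match. Spacers run 0–8, the
full grammar range rather than the narrower DR0–DR5 range reported for
any single receptor.

Strand handling exploits a symmetry: the IR and ER pattern sets are
closed under reverse complement, so one forward pass finds each IR/ER
footprint exactly once; DR is scanned on both strands (a minus-strand DR
appears forward as rc(h2)·N^n·rc(h1)). The scan window is the 250-nt
interval [center − 125, center + 125), truncated at contig ends.

Per-peak summaries use one *best* element — fewest mismatches, ties
broken DR < IR < ER, then smaller spacer, leftmost start, + strand —
because per-type percentages are only interpretable when each peak
contributes once and a "none" category completes the table. At the
default budget the scanner is a sensitivity instrument: random 250-mers
carry on the order of one chance ≤2-mismatch element, so "none"
fractions shrink accordingly; analyses that need the planted/true rate
alone (e.g. recovery tests) run the same scanner at budget 0, where
chance hits are impossible on background scrubbed of exact elements.
The proximal-vs-distal comparison is a pooled two-proportion z-test with
Haldane–Anscombe (+0.5) correction when any cell is zero.

## Knockdown integration

Fold changes are pseudocount ratios on FPKM, (kd + ε)/(ctrl + ε) with
ε = 0.01 exposed in the API; a negative-binomial count model is
deliberately out of scope — the calling rule is stated on FPKM and fold
change, and the cutoffs (fold change ≥2 interpreted symmetrically,
FPKM ≥ 0.1 in knockdown or control) are what define the sets. "Expressed"
means FPKM ≥ 0.1 in at least one of the three conditions. Direction
vocabulary is kept two-sided in all outputs (induced-after-knockdown ≡
repressed-by-the-factor) to prevent sign confusion.

The cohort shift test is Welch's two-sample two-tailed t on log2 fold
changes, cohort vs all expressed genes (pooled variance available by
flag); Welch is the robust default when variances are unknown. The
cohort is a subset of the background; at cohort:background ratios below
~1% the induced dependence is negligible, and the null calibration test
checks exactly this regime.

Distal re-assignment finds, for each >10-kb peak, the common-DE gene
with the nearest TSS, using the same tie-break as annotation, and
summarizes unique target count, median |distance| and the induced
fraction *of genes* (not of peaks).

## Conservation

Two widths are used deliberately: positional profiles default to ±250
around the center (a 500-nt view), per-peak means to 250 nt (±125); both
are parameters. Matched controls are sampled uniformly on the same
chromosome, accepted when the GC difference is within ±0.02 and the
interval overlaps no peak window; the overlap exclusion (flag-reversible)
keeps real binding sites out of the null. On exhaustion of the attempt
budget (default 1000) the tolerance doubles — the tolerance actually in
force is recorded on every control — and saturates at 1.0, where only
the overlap constraint can still fail. One control per peak by default.
Strata with fewer than two peaks are skipped with a warning rather than
producing a degenerate test.

## Mark co-localization

"Within ±2 kb of a distal peak" is interpreted as flanking the peak
*interval* ([start − 2000, end + 2000), half-open), matching "immediately
adjacent"; center ± 2 kb is available by flag. Marks are evaluated
independently (rows are not exclusive); the aggregate is the union of
per-mark overlapping peak sets, so it is exactly ≥ the per-mark maximum.
Overlap queries use an interval tree; tests cross-check against a
quadratic all-pairs scan.

## Synthetic-data generator

The generator emulates the downstream products of a differentiating-cell
ChIP-seq/RNA-seq study so that every stage has recoverable ground truth:

* **Genome**: 3 chromosomes × 2.5 Mb of i.i.d. background at GC 0.41,
  rejection-sampled until no repeat element exists at 0 mismatches, so
  exact elements found later are exactly the planted ones. Residual
  ≥1-mismatch chance hits remain, as in a real genome.
* **Genes**: 30 per chromosome in the first 1.8 Mb (lengths 5–20 kb,
  1–8 exons tiling the transcript); the gene-free tail guarantees
  gene-desert space. Layout capacity was chosen once so that every
  region-class band can host its share of ~1,000 peaks.
* **Peaks**: placed per a class mixture (defaults chosen so ~48% of peaks
  are >10 kb from genes and ~25% are promoter-proximal, the observed
  early-stage conditions); every placement is verified with the
  production classifier before acceptance, and an unplaceable class
  raises an error naming it. Centers keep ≥260 bp separation (disjoint
  scan windows); gene-distal peaks keep ≥5 kb so planted mark flanks do
  not contaminate neighbours. Because near-TSS space is
  separation-limited, the realized proximal fraction settles at ~21–22%
  rather than 25%; this is a placement-pressure artifact accepted as is.
  Enrichment decays exponentially with |TSS distance| under lognormal
  noise.
* **Motifs**: per-stratum plant rates default to the observed
  proximal/distal frequencies (DR1 0.28/0.08, DR4 0.03/0.16, ER6
  0.03/0.11, IR1 0.08/0.16; intermediate rates elsewhere). Planting uses
  exact per-stratum counts (largest-remainder apportionment, shuffled
  assignment) rather than per-peak Bernoulli draws, so recovery tests
  measure the scanner rather than planting noise. Planted elements are
  exact-consensus with random half-site choices (DR1 spacers drawn from
  {A, G}); junction-created accidental exact elements are re-randomized,
  with the whole element redrawn if an accidental element falls inside
  the footprint.
* **Conservation**: a truncated Gaussian bump (σ = 60 bp; height 0.6
  proximal / 0.4 distal / 0.5 otherwise) at each peak center on an
  otherwise-zero track.
* **Expression**: background FPKM lognormal (μ = 0, σ = 2.2 on the
  natural log, putting ~15% of genes under the 0.1 floor); planted
  responders get control FPKM ≥ 1 and fold change 4 (or ¼) under
  multiplicative lognormal noise σ = 0.1, far from the 2× cutoff in both
  directions, so planted labels are recoverable essentially without
  error. 20% of genes respond to at least one shRNA; 61% of responders
  are common to both (making the common set ~76% of either single-shRNA
  set); 80% of responders are induced after knockdown.
* **Marks**: per-mark fractions of distal peaks (0.06–0.34) receive an
  interval inside their ±2 kb flank, placed to avoid other distal peaks'
  flanks where geometry allows; 50 background intervals per mark avoid
  all distal flanks. The manifest records the overlaps that actually
  hold after placement.

Everything derives from one `numpy` generator seeded by the caller;
bundles are byte-identical across runs of the same seed.

What the generator does **not** emulate: read-level noise and peak-caller
artifacts, spatial correlation of chromatin state, isoform structure
(each gene-model row is one assignable unit), inter-gene expression
correlation, and realistic sequence composition (no repeats, CpG
islands or N-runs). Passing recovery tests therefore certify the
pipeline's correctness on well-specified inputs — classification logic,
grammar matching, threshold rules, statistics — not robustness to
upstream noise in real data.

## Problem sizes and numerical choices

Tests run on bundles of 40–150 peaks on 1–2 small chromosomes (seconds
each); the rate-recovery analysis uses 500 peaks per stratum on a
6-chromosome genome, sizes chosen to make binomial confidence intervals
meaningfully tight while keeping the suite fast. Calibration of the
cohort test uses 1,000 null replicates (Kolmogorov–Smirnov uniformity at
α = 0.01) and 500 power replicates at a −0.5 log2 shift, n = 130 vs
15,000, σ = 1. Statistical degeneracies are handled explicitly: equal
vectors give t = 0/p = 1 without invoking the t distribution; zero cells
get continuity correction; empty strata raise or skip with a warning as
documented per function.

## Known limitations

* Multi-isoform genes are not collapsed; callers wanting gene-level
  assignment should pre-select one representative transcript per gene.
* The scanner scores matches by mismatch count only (no PWM weighting or
  information content), so it cannot rank two same-count matches by
  affinity.
* `assign_distal_to_de` falls back to cross-chromosome assignment (with
  distance reported as missing) only when a chromosome carries no DE
  gene at all.
* The conservation null assumes GC and length are the relevant matching
  covariates; real backgrounds may differ in repeat content or mappability.
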
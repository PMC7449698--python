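# Methods

## Coordinate and signal model

All coordinates are 0-based half-open `[start, end)` (BED convention); GFF3
input is converted at the boundary (`start−1, end`). Coverage is a dense
per-base, per-strand depth vector per chromosome. "Downstream" is always
taken in the direction of transcription, and windows clamped at chromosome
edges are reported as raw sums over the surviving bases, never rescaled — a
rescale would silently inflate the extension index of edge features. A fully
clamped window excludes the feature (reported, not silently dropped).

Region signal is the *sum of per-base depth* (area) times the track's scale
factor, not a read count. For paired mutant/WT statistics the distinction is
a per-feature constant that cancels in every ratio; exact read-count parity
with count-based quantifiers is therefore not claimed, ratio parity is.

## Spike-in normalization

Each sample carries the read count mapping to a fixed-proportion foreign
genome (9:1 experimental:spike-in mixture of input material). The scale
factor is `C / spikein_reads` with `C = 1e6` (per-million-spike-in-reads).
The constant is arbitrary — every downstream quantity is a ratio of scaled
signals — and configurable. Scaling is lazy: the raw depth vectors are
shared, only the track's scale changes, so raw-depth operations (de novo
segmentation) and normalized operations coexist on one dataset.

log2-ratio tracks use a pseudocount of 1 per base and are computed as
`log2(a+1) − log2(b+1)` rather than `log2((a+1)/(b+1))` so that swapping the
two tracks negates the result bit-exactly.

## 3' extension index

`3'EI = (S_mut + ε)/(S_wt + ε)` over the 150 bp window downstream of the TES,
with ε = 1 normalized unit by default. The pseudocount prevents division by
zero at silent windows and is deliberately prominent in the configuration and
output headers (ε = 0 is available and raises on silent WT windows). Flagging
is inclusive: `3'EI ≥ 1.5`. The flagged fraction is non-increasing in the
threshold, which the tests assert.

## De novo segmentation

Bases with depth strictly greater than 20 are marked, maximal runs taken,
and runs separated by ≤ 5 below-threshold bases merged. Strictness follows
the script-level description of the procedure; a `--min-depth-inclusive`
flag restores ≥. "Within 5 bp" is read as gap ≤ 5 (standard merge-distance
semantics) and is configurable. With run-gap semantics a single merge pass
is already a fixpoint; the implementation asserts this. Segmentation runs on
raw depths — its threshold is defined on raw reads, so the scale factor is
ignored.

Matching a reference feature to a segment maximizes overlap, breaking ties
by longer segment then leftmost start, and reports the signed 3'-end offset
in the direction of transcription (positive = extended).

## Boundary re-annotation and orientation

The 5' TU boundary is the closest same-strand +1 nucleosome position
strictly upstream of (outside) the CDS; the 3' boundary the closest
same-strand CPS downstream of (outside) the CDS. Point sites exactly at the
CDS 3' edge count as outside (the half-open interval excludes them). Genes
missing either site are dropped and reported — no boundary is ever guessed.
Equidistant candidates resolve to the first in coordinate-sorted order.

Orientation uses the single closest *non-overlapping* neighbor by
edge-to-edge distance, ignoring strand; distance ≤ 500 bp counts as close
(the cutoff read as inclusive; configurable). Same-strand neighbors give
*tandem*; for opposite strands the label follows which ends flank the gap —
when the leftmost unit of the pair points rightwards the 3' ends face
(*convergent*), otherwise the 5' ends face (*divergent*). Labels are
per-gene: a gene's closest neighbor need not reciprocate, so pair-level
consistency is not asserted.

## Class fold change and window statistics

Class folds pool signal across the class before the ratio — one number per
class — which is robust to individual zero-signal features; a per-feature
averaging mode exists behind a flag. Anchored window signals
(`region_set_signal`) accept any offset pair around the TES or CPS and work
identically on RNA-seq, 4tU-seq, MNase-seq and ChIP-seq tracks. Two window
sets are compared with a two-sided Wilcoxon rank-sum test: exact null
distribution for tie-free samples of ≤ 20, normal approximation with tie
correction otherwise, and p = 1 by convention when every value is identical.
The post-CPS RNA comparison reuses this same rank test.

## Aneuploidy screen

Per chromosome, the mean scaled depth (strands pooled) in test and reference
gives a log2 ratio; subtracting the across-chromosome median removes any
residual global scale difference, and `|re-centered ratio| > 0.32` (≈ 1.25×,
halfway to the 1.5× signal of a one-extra-copy diploid chromosome) flags the
chromosome. No sharper numeric criterion is standard, so the threshold is
configurable and the report always carries the raw ratios. Chromosomes with
zero reference coverage are *indeterminate*, never silently passed. A
companion helper removes flagged chromosomes from any annotation list so
every statistic can be recomputed on the euploid genome.

## Synthetic data generator

The generator emulates the *structure* of the real data, not its sequence
content: a toy genome (three 90 kb chromosomes by default) packed with
protein-coding genes (1–2 kb), snoRNAs (100–300 bp, 73 by default) and
optional ncRNA classes (300–800 bp), placed with 400–800 bp intergenic gaps
on random strands via balanced fill across chromosomes. Each gene gets a +1
nucleosome dyad 60 bp upstream of its CDS 5' end and a CPS 120 bp downstream
of its 3' end (the toy convention; real +1 calls may be dyads or edges).

Coverage is a plateau model at a sample depth (default 50×): every feature
is expressed on its own strand, and — the one modeling choice that matters —
every feature also leaks a basal plateau at full depth into its 150 bp
post-TES window in *every* sample. Termination is never perfectly sharp, and
the extension index is a ratio: the designed mutant effect multiplies this
baseline (`d·fold` in the mutant vs `d` in WT), so a designed fold is
recovered as the 3'EI up to the ε floor (within 1% at default depth).
Without the baseline the WT denominator would sit at ε and the index would
not equal the designed fold. Mutant samples additionally scale class
features by per-class folds, add antisense plateaus at a configurable
fraction of the sense depth, and multiply whole chromosomes by aneuploid
copy ratios. `noise="poisson"` replaces each base with an integer Poisson
draw of its mean (per-sample substream derived from the seed and sample id);
`noise="none"` keeps exact plateaus. Identical (config, seed) inputs give
byte-identical files.

The spike-in is a scalar read count, not a second genome's tracks: the
normalization contract needs only the count. Its default is one ninth of the
*baseline* (wild-type-equivalent) coverage area — the 9:1 mixture is of
input cells, identical across samples — so paired samples at equal depth get
equal scale factors by construction. Passing explicit counts exercises the
full normalization path, including deliberately unequal factors.

What the generator does not emulate: read-level sampling (fragment lengths,
GC bias, mapping artifacts), splicing, transcription-level heterogeneity
between genes, and positional decay of readthrough signal (the optional
exponential tail beyond the window is not modeled; the statistics only see
windowed sums). Passing tests therefore demonstrate the *analysis* is
correct under the stated signal model, not that the model captures every
property of real libraries.

## Pipeline determinism and problem sizes

The orchestrated run writes only deterministic artifacts (sorted-key JSON,
fixed-order TSV, 6-significant-digit floats); timings and log lines go to
stderr only, so re-running on identical inputs is byte-identical. Test and
benchmark problem sizes — ≤ 10 kb chromosomes for oracle equivalence
(hundreds of random draws), a 73-snoRNA genome for recovery experiments, 20
Poisson replicates for sensitivity/specificity and the ploidy screen — were
chosen as the smallest sizes at which every effect of interest is
unambiguous at the default depth.

## Known limitations

- Signal is depth-area, not fragment counts; statistics that depend on
  read-length structure (e.g. junction usage) are out of scope.
- The orientation classifier labels genes, not deduplicated pairs.
- bigWig input is not supported; coverage I/O is text bedGraph per strand.
- The rank test's exact branch requires tie-free data; tied small samples
  fall back to the corrected normal approximation.
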
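# Methods

## The model

`tepool` detects transposable-element (TE) polymorphisms segregating in a
*pool* of sample genomes sequenced with paired-end reads and mapped to a
reference genome, and estimates each event's population frequency.  Two
event classes are handled:

**Sample-specific insertions.**  A TE present in some sample genomes but
not in the reference betrays itself through discordant read pairs: one
read (the *anchor*) maps uniquely to genomic sequence while its mate has
no acceptable placement (or only non-unique placements) and instead
matches a TE consensus.  The family is assigned by ungapped fewest-
mismatch comparison of the mate against both strands of every consensus
(default budget 3 mismatches, `N` is a wildcard); ties between families
are ambiguous and discarded rather than guessed.  The insertion
orientation follows from FR-library geometry: the mate is sequenced on
the strand opposite the anchor, so the element is forward exactly when
the mate's consensus strand differs from the anchor strand.  Each anchor
bounds the junction within an *interval estimate* — from the anchor's
inner end, one mean insert size into the genome.  Supports of the same
family and orientation whose interval estimates overlap by at least 1 bp
are clustered; the running intersection of member intervals is the
refined interval estimate (chains whose common intersection would become
empty are split greedily left-to-right, so the refined interval is always
a true intersection).

**Sample-specific absences.**  A reference-annotated TE copy missing from
sample genomes yields read pairs whose mapped span is significantly
longer than the library insert: both mates unique, FR orientation, outer
span above `insert_mean + 3*insert_sd` but below 10 kb (larger spans are
treated as mapping artifacts).  A candidate pair supports absence only if
at least one annotated copy lies fully between the inner read ends and
the outer span minus the summed copy lengths falls back inside the
3-sigma insert band.  Pairs spanning the identical copy set form one
event.

**Junction refinement.**  Interval estimates are widened by 20 bp and
soft-clipped reads whose clip point falls inside the window are
collected.  A clip is junction evidence only if it is at least 7 nt long
and matches its expected source *perfectly*: the event's consensus
(oriented by the insertion strand) for insertions, or the genomic
sequence continuing on the far side of the deleted copy for absences.
Per side, the clip point supported by the most reads wins (ties to the
smaller coordinate).  Junctions are side-specific: `junction_plus` comes
from reads aligned upstream (clip at the alignment's right end),
`junction_minus` from downstream reads.  The signed difference
`junction_plus - junction_minus` is the target-site duplication (TSD)
length; negative values indicate target-site deletion.  Without accepted
clips, insertions fall back to the interval midpoint and absences to the
annotated boundaries.

**Frequency estimation.**  For each event, `T` counts distinct read pairs
supporting it (discordant pairs plus accepted clip reads; a pair
contributing both counts once) and `R` counts concordant, both-unique
pairs whose fragment spans an estimated junction with at least 7 bp on
each side.  The population frequency is `T/(T+R)`.

*Per-junction accounting of R.*  The ratio estimates the carrier fraction
only if presence and reference evidence are collected over commensurate
fragment-placement windows.  An insertion creates two junctions in the
sample genome (upstream and downstream flank of the element) and both
feed `T`; a single reference fragment spanning the site is consistent
with the reference allele at *both* estimated junctions, so `R` sums the
two per-junction counts.  An absence event has a single novel junction
(the deletion joint) feeding `T`, while a reference-allele fragment can
span only one of the two annotated boundaries (the element is longer
than a fragment), so `R` averages the per-boundary counts.  Without this
accounting the insertion frequency is overestimated by roughly the ratio
of the two windows (measured ~0.33 for a designed 0.2) and the absence
frequency underestimated by about half.  With it, mean absolute errors
on simulations are 3-5%, inside the published error levels this package
reproduces.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `insert_mean`, `insert_sd` | estimated from BAM | fragment-length statistics (outer distance); estimator: median and 1.4826*MAD of the first 100k concordant templates |
| `span_z` | 3 | concordance band half-width in insert-size SDs |
| `max_span` | 10000 bp | span cap for absence evidence |
| `max_mismatch` | 3 | TE-consensus assignment budget (mirrors the genome-mapping tolerance) |
| `mapq_unique` | 20 | minimum MAPQ for "uniquely mapped" (aligner-portable stand-in for a unique-tag) |
| `clip_window` | 20 bp | interval widening for clip collection |
| `min_clip` | 7 nt | minimum perfect clip length |
| `ref_flank` | 7 bp | fragment flank required around a junction for R pairs (symmetric with the clip rule) |
| `min_reads`, `min_freq` | 1, 0.0 | reporting filters (a pooled human-data setting would be `--min-reads 9 --min-freq 0.2`) |

Two internal constants express aligner behaviour at junctions.
`HOMOLOGY_SLACK = 5`: when the first bases of the element equal the
reference continuation (junction microhomology), a soft-clipping aligner
extends junction-adjacent anchors a few bases past the true junction; the
anchor-side end of each interval estimate is padded by 5 slots so that
the two sides' estimates still intersect and contain the junction.
`ANCHOR_MIN_ALIGNED = 50`: anchors clipped on both ends, or with fewer
than 50 aligned bases, do not localize anything reliably — they are
typically element-internal reads matching a chance conserved stretch of
a diverged annotated copy.  For the same reason a pair is discarded when
the anchor read itself matches a TE consensus within the mismatch
budget: an element-derived read cannot anchor a new insertion.

Coordinates are 0-based half-open throughout; a junction is the slot
*between* two bases, written as the index of the base to its right, so an
interval estimate covering `insert_mean + 1` candidate slots includes the
anchor's inner end.

## The synthetic-data generator

The simulator emulates the study design used to benchmark this class of
method: a reference genome (uniform random sequence) carrying annotated
TE copies; sample genomes derived from it by inserting full-length
consensus sequences (random family, strand and site, optional designed
TSD) and deleting whole annotated copies; 90 nt paired-end reads with
Normal(500, 50) insert sizes truncated at twice the read length, FR
orientation, uniform substitution errors at 1e-4 and constant base
qualities; and pooled mixtures, either by combining several
independently mutated genomes at low depth (each event then segregates
at 1/n_pools) or by binomially mixing variant and reference pools at a
designed frequency.

Two generator choices deserve explanation:

* **Planted copies are diverged 25% from their consensus.**  Annotated
  reference copies are old, decayed insertions, while new insertions come
  from an active, consensus-like element.  The divergence reproduces the
  regime the detection logic assumes: reads from a new insertion have no
  acceptable placement on the reference (verified: ~1% residual
  mappability at 25% divergence for 90 nt reads under bwa-mem scoring),
  while reads inside annotated copies map uniquely — which is also what
  makes reference (R) pairs at annotated loci countable.
* **Family lengths 611-11123 bp (11 families).**  The lengths span the
  range of real TE consensus lengths.  The longest family exceeds what
  the 10 kb span cap can ever certify as absent (outer span = fragment +
  element length), so its single annotated copy (1 of 20, ~5%) is a
  structural false negative of absence detection — the same mechanism
  that keeps real-data absence sensitivity below 100%.

What the generator does *not* emulate: GC bias, indel errors, PCR
duplicates, quality-score structure, repeat-dense or low-complexity
flanks, nested/fragmented annotation, and divergence between the sample
genomes' element and the consensus.  Passing tests therefore demonstrate
correctness of the detection/estimation logic under the stated read
model, not performance on real libraries, where mappability and
annotation quality dominate the error budget.

## Benchmark problem sizes

The built-in benchmark reproduces the published study design at reduced
scale, chosen so a complete run fits comfortably on one CPU: the
pooled-arm study uses a 2 Mb reference with 20 planted copies, five
independently mutated genomes per dataset at 5X each (25X apparent,
each event at designed frequency 0.2, shared excisions at k/5), four
datasets (20 mutated-genome replicates, ~1.1M read pairs mapped); the
depth/frequency sweep uses a 1 Mb reference at 20X with 10 insertions +
10 excisions per designed frequency in 0.1-1.0.  Mapping uses bwa mem;
the caller itself is aligner-agnostic (any BAM with soft clips and
mapping qualities).

## Evaluation rules

A planted insertion is recovered when a predicted event's interval
estimate brackets the true junction slot and family and orientation are
correct; a planted excision is recovered when an absence event
references the excised copy.  Matching is greedy nearest-first and
one-to-one; unmatched predictions are false positives.  A junction is
*found* if the event reached base resolution and *correct* if a base
estimate lies within 5 nt of a true junction.  Frequency error is the
mean |estimated - designed| over true positives.

## Population statistics

`frequency_change` computes `FC = F - (H + W)/2` for events whose
frequency exceeds 10% in at least one parental pool (below that the
event is flagged non-parental, not scored).  `wf_change_tail(n, delta)`
is the exact drift null for such changes: one generation of binomial
resampling of `n` chromosomes, `P(|X/n - p| >= delta)` maximized over
the parental frequency grid `p in {0, 1/n, ..., 1}`, summed in log
space.  Maximizing over `p` makes the null conservative (the largest
tail any parental frequency could produce).  For `n = 200` and
`delta = 0.3` the bound is below 1e-15, so observed changes of that size
cannot be drift.  `junction_composition` counts mono- and dinucleotides
in 30 bp windows centred on the midpoint between the two strand
junctions against 30 bp background windows 100 bp away on both sides,
and exports the windows as FASTA for external motif discovery.

## Numerical and degenerate-input choices

* Event output is deterministically sorted (contig, start, family);
  clustering sorts supports before the sweep, so results are independent
  of input order.
* Clip-point ties break to the smaller coordinate.
* TE-assignment ties between families are ambiguous: counted and
  dropped, never guessed.
* Interval estimates clamped at contig ends; a clamp that empties the
  interval discards the support with a warning.
* `estimate_frequency` requires `T >= 1`; events losing all support are
  dropped, not reported with frequency 0.
* The absence R average rounds half away from zero to stay integral.

## Known limitations

* Compound events closer than one insert size (e.g. an insertion next to
  an excised copy) displace each other's interval estimates; the
  affected event may be reported at a shifted locus.
* Microhomology between the element ends and the target site makes the
  junction coordinate ambiguous within the homology tract: clip points
  shift outward by the homology length on each side, which inflates the
  apparent TSD length accordingly.  This is inherent to split-read
  junction calling, not specific to this implementation.
* Absence of elements longer than `max_span` minus one fragment length
  is structurally undetectable; such loci are reported only if shorter
  spanned-copy subsets exist.
* The caller cannot distinguish a sample-specific excision from a
  reference-specific polymorphic insertion; both are reported as
  `absence`.
* De-novo elements absent from the consensus library are invisible, as
  are events whose anchors fall in non-unique sequence.
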
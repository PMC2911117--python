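# Methods

## Problem and model

ChIP-seq pipelines ordinarily discard reads without a unique genomic
alignment, which silences the repetitive fraction of the genome. repeatchip
estimates the *average* fold enrichment of a chromatin mark over a set of
homologous repeat sequences — a repeat type (consensus plus all annotated
genomic copies), or any grouping of such sets — by pooling the reads that can
be attributed to that set unambiguously, even when they cannot be placed at a
single position.

Counts are modelled as Poisson: the ChIP library contributes `s` reads to the
set out of an effective dataset of size `S`, the control (input or histone H3)
contributes `c` out of `C`. With a non-informative half-count prior the fold
enrichment and its equal-tailed interval are

    theta_hat = C (s + 1/2) / (S (c + 1/2))
    lambda(x) = theta_hat * F[x, 2(s + 1/2), 2(c + 1/2)]

with the interval bounds given by `lambda` at the `alpha/2` and `1 - alpha/2`
F-quantiles (`alpha` = 0.05 by default). This is the posterior of a ratio of
two Gamma rates: both bounds are computed with the lower-tail quantile and
sorted, which makes the result independent of tail convention. The interval
is validated two ways: against an F-free Monte-Carlo oracle (quantiles of
sampled Gamma-ratio posteriors) on a grid of `(s, c)` configurations, and by
empirical coverage under Poisson resampling (the acceptance script reports
the latter: ~95% at `theta = 2`, expected control count 100, 10,000
replicates).

## Assigning reads to repeat types

A repeat *assembly* concatenates, per type, the canonical (consensus)
sequence and every RepeatMasker-annotated instance with `flank_bp` (default
13, configurable as half the read length) of genomic flank, separated by
80-'N' spacers. Bases outside {A,C,G,T} mismatch everything, so no admitted
alignment can bridge a spacer; each alignment therefore lies within one
segment, and segments map back to their genomic or consensus source.

Alignment is ungapped, both strands, with at most `max_mismatch` (default 1)
mismatches, and is *fully sensitive*: the read is split into
`max_mismatch + 1` chunks, so an admissible alignment leaves at least one
chunk exact (pigeonhole); each chunk's leading k-mer (k = min(16,
floor(L_min/(max_mismatch+1)))) is looked up in an exact k-mer index and all
candidates are verified. The test suite asserts set-equality with an
exhaustive sliding-window oracle. Base qualities, gaps and paired ends are
out of scope: at 26–36 bp with <= 1 mismatch there is no other score, so
quality strata are defined by mismatch count alone.

A read is then

- **assigned** to type T if all of its equal-best (minimum-mismatch) hits
  fall in T — multiple positions within T are allowed;
- **cross-type ambiguous** if equal-best hits touch two or more types (these
  reads are retained with their hit-type sets; the phylogeny recovers them);
- **masked** (optional third condition) if an assigned read also aligns, at
  no more mismatches than its best assembly hit, to genome sequence not
  contained in any flanked annotated instance of its type — guarding against
  un-annotated repeat copies;
- **unmapped** otherwise.

The effective dataset size `S` (or `C`) is the number of reads with at least
one hit in the genome assembly or the canonical library; it is deliberately
insensitive to the repeat annotation itself.

Per-instance counts (used only for instance-level trees) attribute a
within-type multi-hit read fractionally, 1/(number of instance segments hit),
preserving totals; type-level counts are always integers.

External aligners can substitute for the built-in one through SAM ingestion
(`read_sam_hits`): records must carry NM tags, and gapped/clipped or
NM > max_mismatch records are dropped. A round-trip test asserts identical
type counts between the two routes.

## Significance scores

The printed display anchors a Z of 3.1 to a one-sided p of 1e-3 but does not
fix the test statistic. We use the exact two-sided binomial test of `s`
successes in `s + c` trials against `p0 = S/(S+C)`, signed by the direction
of `theta_hat` and folded to a one-sided normal quantile
`Z = sign(theta_hat - 1) * Phi^-1(1 - p/2)`, capped at ±10 (p below ~7.6e-24
saturates the cap). This reproduces the anchor exactly and is well-behaved at
small counts; it is documented as this package's choice, not asserted as the
only possible one. Significance *calls*, however, always come from the CI
(interval excluding 1), so they are independent of the Z construction.

Two estimates are compared as a ratio of two binomial proportions adjusted
for dataset size, using the non-iterative approximate Bayesian construction
of Price and Bonett: half a count added to every count and size, normal
interval on the log scale with variance `1/(s+1/2) - 1/(S+1/2) + 1/(c+1/2) -
1/(C+1/2)` per estimate. Verified by parametric-bootstrap coverage (~95%
under equal true proportions).

For clustering, non-significant cells and significant depletion are set to 0
(depletion is retained for display, coded blue; non-significant cells white;
enrichment red) and rows are agglomerated with Ward linkage on Euclidean
distance. Family over-representation within a cluster uses the upper-tail
hypergeometric p per family, Bonferroni-corrected across the families tested
(the conservative default; configurable).

## Input-free relative normalization

With many marks and no input, each repeat type's percentage of assigned
reads (100·s/S) across the marks forms its own background. The marks with
the top `n_omit` (default 5 of 21) point percentages are set aside as
enrichment candidates; each retained percentage is resampled 100 times from
the Jeffreys Beta posterior `Beta(s + 1/2, S - s + 1/2)` — matching the
half-count prior of the enrichment model, since the source text names only
"the Beta distribution" — and a Gaussian is fitted to the pooled draws
(pooling all draws is our reading of fitting "using all percentage ratios").
Every mark, including the trimmed candidates, is scored
`Z = (ratio - mu)/sigma`; `sigma` is floored at `1e-12·max(|mu|, 1)` for
degenerate tables. Only enrichment is callable: the background level itself
absorbs depletion, so negative Z-scores carry no significance.

Calibration note: trimming the top 5 of 21 *null* marks biases `mu` and
`sigma` slightly low, so the realized null tail rate at Z > 3.1 need not
equal the nominal 1e-3 exactly; empirically it stays within the same order
of magnitude (the property test asserts the band [1e-4, 1e-2], and measured
values sit near 6e-4), while planted 5–6x enrichments at expected counts
>= 100 are recovered with sensitivity >= 0.9.

## Enrichment phylogeny

Each node is a set of leaf sequences (repeat types, or instances of one
type). A read is *aligned* to a node if any equal-best hit touches a member
and *unique* if all equal-best hits do; the node's enrichment is estimated
from its unique ChIP and control counts. Similarity between nodes is the
Jaccard ratio of shared to total aligning reads — the "total aligning to
both sets" is read as the union, since the intersection reading would make
the ratio identically 1. The tree is built greedily bottom-up, merging the
most similar pair (ties broken lexicographically on the smallest member
name, so the topology is independent of input order) and recomputing read
sets exactly after each merge; classic Saitou–Nei neighbor joining is not
used because the read-set measure is not an additive distance. Branch
*gain* is the number of reads unique to the node but not to its children;
gains are provably non-negative and sum to the root's unique count (every
uniquely assignable read is gained exactly once), and both facts are
asserted on every constructed tree. Display lengths are `log10(1 + gain)`;
node Z-scores are capped at ±10.

For instance-level trees, reads with any admitted hit in *another* repeat
type are discarded first; hits in the same type's canonical segment are
treated as neutral (ignored, not discarded) because the consensus represents
the very instances under study — discarding on consensus hits would empty
the tree exactly in the near-identical-copy regime the method targets.
Topology uses ChIP reads only; the control enters only the per-node
annotation (a flag allows combining).

## Synthetic data

The generator emulates the study conditions at desk scale: random canonical
sequences; annotated instances planted as i.i.d.-diverged (and optionally
truncated) copies spread through a uniform-random background genome;
optional un-annotated partial copies (30–70% fragments) that exercise the
masking condition; single-end 26–36 bp reads. Defaults follow the source
protocol where it states values: 32-bp reads, <= 1 mismatch, 13-bp flanks,
80-N spacers, positional error rates rising linearly (the shape is our
choice; only the endpoints are given) from 5.4e-3 to 1.0e-2 across the read,
uniform off-diagonal substitution matrix (configurable), SNP rate 8.3e-5,
100-fold assembly resampling for mis-assignment rates. Where no value is
stated, defaults are desk-scale choices a practitioner would call realistic:
canonical lengths ~300–400 bp, 3–4 instances per family at 5–8% divergence,
background genomes of 15–30 kb, libraries of 2,500–9,000 reads — large
enough for expected per-type counts of 100+ while keeping the full suite
fast.

ChIP reads over-sample each planted type's footprint by its true `theta`
with the background weight lowered so that total sampling mass equals the
input's (fixed sequencing depth: enrichment crowds out background). This
makes the planted `theta` *exactly* the ratio of ChIP to input read
proportions — the estimand — rather than a raw weight whose measurable
effect would shrink as other families' enrichment inflates the ChIP
denominator. No fragment-length or shift modelling is included: the
estimator uses only counts, never positional offsets.

What passing tests show — and do not. The generator's reads are uniform
within their source intervals, errors are independent across positions and
reads, and copy number is known; real libraries have PCR duplicates
(deduplication is off by default, mirroring the source protocol, with a
flag), coverage biases, and unknown, cell-variable copy numbers (which is
precisely why the estimator normalizes by a control library). Recovery of
planted `theta` therefore validates the estimator's logic and calibration,
not robustness to library artifacts.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; RepeatMasker input is
  1-based inclusive; BED output is 0-based half-open; strand 'C' maps to '-'.
- Minus-strand instances are stored as plus-strand genomic slices; strand is
  handled by aligning each read's reverse complement.
- Overlapping instances of different types are all kept; the uniqueness
  conditions resolve the ambiguity.
- Reads containing N are allowed; N counts as a mismatch everywhere.
- A type with zero instances contributes its canonical alone in combined
  mode (no trailing spacer); instance-only assemblies with no instances at
  all are an error.
- All-zero clustering matrices and single-leaf trees degrade to trivial
  results with a warning rather than an error.
- All randomness flows through one seeded NumPy generator per entry point;
  pipeline manifests record parameters, seeds and output checksums, and
  reruns with the same seed are byte-identical.

## Known limitations

- Enrichment is an average over the set; a result can be driven by a few
  instances (the instance-level tree is the tool for probing that).
- The greedy tree is not globally optimal; exhaustive search is
  combinatorially infeasible and deliberately out of scope.
- Relative normalization cannot call depletion, and assumes most marks are
  unenriched at any given repeat.
- The aligner is designed for full sensitivity at desk scale (fixture
  genomes of tens of kilobases); genome-scale runs are expected to go
  through an external aligner and SAM ingestion.
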
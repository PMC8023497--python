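# Methods

## Scope and data model

`mitoarch` treats an annotated mitogenome as a circular molecule of
length L with an ordered list of features, each a label, category (PCG,
tRNA, rRNA, control-region, other-noncoding), strand, and 1-based
inclusive coordinates; `end < start` encodes a feature spanning the
origin, whose length is `end − start + 1 + L`. Gene content is never
enforced (many bivalves lack *atp8*), labels are canonicalized
case-insensitively (COI→cox1, 12S→rrnS, …), and the duplicated Leu/Ser
tRNA isoacceptors are resolved by anticodon (TAG→trnL1, TAA→trnL2,
TCT→trnS1, TGA→trnS2) when the input names only "trnL"/"trnS". Unknown
labels are retained as other-noncoding with a warning rather than
aborting a parse, since gene complements vary across taxa.

The packaged reference is the transcription of the published *S. minima*
(MT375556) tables: the 36-feature annotation, the per-region
composition/skew table, and the 64-codon count table. Three internal
inconsistencies of the published tables are deliberately *not* resolved:

* cox2 is 948 bp in the composition table but 685 bp by its coordinates;
  `Mitogenome.validate(reference_sizes=...)` flags the conflict.
* the trnF→cox1 spacer is printed as 273 bp, but only 274 closes the
  circular conservation identity at 17,064 bp; the computed value is
  reported.
* the codon table totals 5,684 codons, more than the 3,754 implied by
  11,262 bp of coding sequence; the table is treated as an opaque input.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed at full precision
from counts or percentages (the two agree by scale invariance).
Ambiguous bases are excluded from numerators, denominators and
percentage bases; U is read as T. Printed output rounds percentages to
2 dp and skews to 3 dp, **half away from zero** — required to recover
published values such as 0.616 from 0.61605; Python's bankers' rounding
would disagree on such boundaries. Category regions (PCGs, tRNAs,
rRNAs) concatenate coding-strand sequences in genome order from the
first feature after the origin; light-strand features are
reverse-complemented first. "CR" resolves to an annotated
control-region feature if present, else to the largest noncoding
interval.

## Circular gap accounting

Gap after gene i is `start(i+1) − end(i) − 1` with `start` lifted by L
on the closing adjacency and `end` lifted for origin-spanning features;
features are compared in sorted start order. Positive gaps are
noncoding regions, negative gaps overlaps, and the conservation
identity Σ lengths + Σ signed gaps = L is asserted on every fixture and
synthetic genome — it is the invariant that justifies trusting the
computed 274 bp wrap gap over the printed 273. Only pairwise-consecutive
overlaps are modelled; a feature reaching past its next-but-one
neighbour raises a validation error. The control region is the largest
noncoding interval, ties to the lowest start. Terminal codons: start =
first coding-strand triplet; a length ≡ 1 (mod 3) ending in T is the
incomplete stop "T(AA)", ≡ 2 ending in TA is "TA(A)" (polyadenylation
completes both); the trailing partial codon is excluded from codon
counting.

## Hairpin search

`find_hairpin` is purely combinatorial: every placement (i, j) of an
outermost pair is extended inward while bases pair, capped so the loop
never shrinks below `min_loop`; candidates must reach `min_stem` pairs
and keep the loop ≤ `max_loop`. The winner maximizes stem pairs, ties
to smaller loop then 5′-most placement. Pairing is Watson–Crick with
G·T wobble optional. Defaults (min_stem 6, min_loop 3, max_loop 30,
WC-only) recover the published 34-nt OL element, for which exhaustive
search finds a 10 bp stem with a 14 nt loop; the published "18 bp stem,
16 bp loop" is internally ambiguous (18 plausibly counts both arms) and
is not encoded as truth. Free-energy folding is out of scope. The
search is O(n²) with early termination — sub-second on control-region
sized queries and verified against an independent enumeration oracle on
all sequences ≤ 40 nt in the test corpus.

## Codon usage

Synonymous families come from Biopython's table 5 (so UGA sits with UGG,
AGA/AGG extend Ser to 8 codons, AUA joins Met, Leu is a 6-codon
family, UAA/UAG form a stop family). RSCU uses these merged families —
required to reproduce values like RSCU(UUA) = 2.46 — while amino-acid
composition reports the split families conventional in mitogenomics
(Leu1 = CUN, Leu2 = UUA/UUG, Ser1 = AGN, Ser2 = UCN), with stops
excluded from the denominator — required to reproduce Phe = 11.66%.
Both groupings are explicit in `genetic_code_families` /
`split_families`. Counting operates either on a provided count table or
on genome sequences (consecutive coding-strand triplets, incomplete-stop
tails dropped). One known reference discrepancy: the published "leucine
2 = 8.52%" computes to 8.51% from the published counts (462/5,431);
the recomputed value is reported.

## Gene-order comparison

Orders are label sequences with per-gene signs. Because labels are
unique, adjacency bookkeeping suffices: a shared block is a maximal run
of adjacencies of order *a* preserved in order *b* (same direction;
in signed mode a reversed run with flipped signs also counts, flagged
`reversed`). Orders over unequal label sets are first restricted to
their common labels — contiguity after restriction, the convention used
when tRNAs are ignored across taxa — and the pipeline report records
the dropped labels. Breakpoint distance counts adjacencies of *a*
absent from *b*: unordered pairs when unsigned (so a reversed pair
still matches, giving distance 2, not 3, for a two-gene swap), and
strand-canonicalized tuples when signed; circular orders contribute n
adjacencies, linear n−1. `conserved_fragments` intersects preserved
adjacencies across all orders and additionally requires a consistent
orientation per order within each run. Unsigned comparison is the
default because the reference taxa encode all 36 genes on the heavy
strand. Both operations are validated against brute-force
all-substrings / adjacency-enumeration oracles on hundreds of random
permutations (≤ 10 labels) and are rotation-invariant by construction.

## Synthetic genomes

`SynthSpec` → `synth_genome` lays out genes (default: the 36-gene
reference complement, sizes from the reference annotation, optionally
block-permuted by `k_block_moves`), draws spacers to meet an
approximate target length, reserves one junction for a control region
of `cr_length` containing a planted hairpin, and fills sequence from
per-base probabilities derived from the targets
(p_A = f·(1+s_AT)/2 with f = AT%/100, etc.). Protein-coding genes get a
start codon from {ATG, ATA, ATT}, internal codons sampled from codon
weights, and a TAA/TAG stop truncated when the gene length is not a
multiple of 3 (planting incomplete stops). Default codon weights are a
per-position product distribution **calibrated by a fixed-point
iteration** so that, after excluding the two stop codons, the marginal
base distribution still equals the composition targets; without the
calibration the AT-rich stop exclusion biases realized A+T% by ~1%.
Sequence assembly writes noncoding background first, then tRNA/rRNA,
then PCGs, so overlapping junctions (allowed only where a tRNA is
involved, capped at 20 bp, echoing the observed 16 bp maximum) never
corrupt a coding frame. All randomness flows from one
`numpy.random.default_rng(seed)` in fixed order.

What the generator does *not* emulate: real tRNA/rRNA secondary
structure, substitution processes along a phylogeny, repeats or
heteroplasmy. Passing tests therefore demonstrate correctness of the
accounting and recovery machinery on genomes with the right
*statistical architecture*, not performance on evolutionarily realistic
sequence.

## Test problem sizes and tolerances

Parameter-recovery tests use 20 seeds of ~17 kb genomes with tolerances
±1.0 on A+T% and ±0.05 on skews (binomial noise at that length is an
order of magnitude smaller; the margin absorbs residual structural
bias). The codon-stream goodness-of-fit uses one genome with four
24 kb genes (~32k internal codons), chi-square at α = 0.01. Oracle
comparisons run 50–100 random cases per operation at ≤ 10 labels and
≤ 40 nt, where exhaustive enumeration is instant. Published-value
regressions compare at printed precision (2 dp percentages/RSCU, 3 dp
skews), exactly.

## Pipeline and CLI

`pipeline.run` is deliberately thin: read each input (GenBank or TSV),
emit per-genome TSV reports with fixed column order and rounding (so
reruns are byte-identical), a cross-genome composition table, and a
pairwise order-comparison table for ≥ 2 inputs; collect every parser
warning in `run.log`; a failing input is reported and skipped without
aborting the rest. The click CLI (`report`, `compare-order`,
`simulate`, `validate`) only parses flags and delegates.
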
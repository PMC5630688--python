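# Methods

This note documents the models, statistics and design choices behind
`islet`, and what the synthetic benchmarks do and do not demonstrate.

## Usage patterns and their similarity

The unit of comparison is the oligonucleotide usage pattern (OUP): the
complete set of 4-mer words of a sequence ordered by descending count,
ties broken lexicographically, unobserved words last.  Two counting
policies exist:

* `direct` (default): the 256 words of the given strand;
* `both_strands_summed`: each word pooled with its reverse complement,
  collapsing to 136 strand-symmetric classes.

Similarity between two patterns over the same word set is the normalised
Spearman footrule, `100·(1 − Σ|Δrank|/⌊n²/2⌋)` percent.  The denominator
is the maximum achievable displacement sum, attained by the reversed
ordering (verified by exhaustive enumeration for n ≤ 6 in the tests), so
the scale is exactly 0–100 with 100 for identical lists.  The footrule
was chosen over rank correlation because it is linear in displacements,
exactly attains both endpoints, and depends only on the two orderings —
no distributional assumptions.

The direct policy is the default because the strand-collapsed alphabet is
nearly blind to mononucleotide composition differences: A↔T and C↔G
shifts cancel under collapsing, leaving GC content as the single strong
axis, which is too little to distinguish many donor signatures.  Strand
collapse remains available for strand-agnostic inputs.

## Window statistics

For a window against its replicon's `GenomeModel`:

* `D` — OUP distance of the window to the whole-replicon pattern,
  divided by the replicon's median window distance at the scan's window
  length and step.  The normalisation makes `D ≥ 1.7` mean "1.7× the
  genome-typical deviation" on any replicon, regardless of how noisy its
  spectrum is.  The median is computed once per replicon.
* `RV` — `(1/n)·Σ_w (obs_w − exp_w)²/exp_w` with expectations from the
  window's own mononucleotide frequencies (zero-order fit).  It measures
  internal structure beyond base composition.
* `GRV` — the same statistic with expectations from the genome-wide word
  frequencies scaled to the window's word total.  It measures total
  deviation from the host signature.
* `V = GRV/RV` — near 1 for windows drawn from the genome's own model
  (both statistics reduce to sampling noise of comparable size), high
  inside foreign inserts (GRV gains the full donor–host difference while
  RV only sees the donor's internal structure).  `V` is NaN (flagged
  degenerate) when `RV = 0`, which occurs only for near-constant windows.

Terms with zero expectation are skipped; windows containing ambiguous
bases skip those 4-mer positions rather than imputing them.

## Detection

Defaults: 8 kb windows, 2 kb coarse step, thresholds `D ≥ 1.7` and
`V ≥ 1.5` (both must hold per window), minimum island length 5 kb,
backtrack of 3 coarse steps for refinement.  A run of one or more
qualifying windows opens a candidate; refined candidates overlapping or
separated by less than the fine step (200 bp) merge before the length
filter.  Replicons are treated as linear; a wraparound insert spanning
the origin would be called as two islands (known limitation).

**Border refinement.**  The coarse run localises an island only to
within a window length.  The refiner scores every position of the
backtracked region with the log-likelihood ratio of the candidate's own
word frequencies (with 0.5 pseudocounts) against the genome background,
and places each border at the CUSUM argmax — the changepoint maximising
the cumulative island-side score.  Expected inside-score is the
donor-vs-background KL divergence per word (positive), outside-score its
negative, so the argmax concentrates within tens of base pairs of the
true junction at the divergences the generator produces.  A windowed
vote (island-content fraction per sliding fine window) was tried first
and abandoned: all straddling windows share the same local core text, so
their errors are correlated and the border landed up to 2 kb off.

**Screens.**  The rRNA screen is a k-mer seed-chain approximation of an
ungapped BLASTN search: exact 16-mers shared with a 16S reference are
grouped by alignment diagonal (band 32), and a group spanning ≥ 300 bp
whose match density implies ≥ 80% identity (Mash-style `q^(1/16)`
estimate) marks the island suspicious.  Flagged islands are kept but
marked, since rRNA operons mimic foreign composition without being
mobile.  Bit-compatibility with BLASTN is not promised.  The keyword
screen is a case-insensitive substring match of product annotations
against {integrase, phage, IS-element, transposase, recombinase,
conjugation, conjugal, mobile element}.  The true-positive extrapolation
`n_unconfirmed_keypositive · 100/56` encodes the empirical rate at which
verified islands carry such keywords (56%).

## Network, representatives, search

Edges exist for pairs at or above the 75% floor; MCL weights are capped
at the 85% ceiling (capping, not deletion, so near-duplicates stay
connected but cannot dominate flow).  MCL is implemented directly:
column-normalised adjacency with self-loops equal to each node's maximum
incident weight, iterating expansion (matrix square) and inflation
(elementwise power, default 2.0) with pruning at 1e-8 until the iterate
changes by less than 1e-6; clusters are the connected components of the
limit support.  Clusters above 50 members are re-clustered on their
induced subgraph at inflation 3.0.  Disconnected components can never
merge, and the partition is invariant to node order (nodes are processed
sorted).

Representatives are chosen greedily: repeatedly take the uncovered
member with the most links in the [75, 85] band to other uncovered
members (ties lexicographic); members within the floor of a chosen
representative count as covered.  This realises an omnipresent cover —
every member is within 75% of some representative — which the tests
verify exhaustively on every generated clustering.

The heuristic search compares a query to all representatives first and
scans only the clusters/subclusters whose best representative reaches
the floor.  Its results are always a subset of the exhaustive scan;
recall is ≥ 0.9 on the default corpus and misses are the documented
price of the heuristic (queries matching a cluster member but not its
representative).

Sequence-homology links are ingested from standard 12-column BLAST
tabular files (e-value cutoff 1e-6, self-hits dropped, duplicate pairs
collapsed to the best e-value) rather than recomputed.  Link profiling
assigns each OUP link to the lowest taxonomic level at which the two
hosts differ (Genome, Strain, …, Domain) from 7-rank semicolon-delimited
lineage strings.

## Flux calls

For a homologous island pair, the four island-to-host-pattern
similarities decide the direction: both islands must prefer the same
host by at least the margin (default 5 percentage points) for a
directional call; everything else is ambiguous.  The rule is exactly
antisymmetric under query/subject swap, and raising the margin can only
turn directional calls ambiguous.  Whole-replicon host patterns are used
(not island-masked core patterns); with heavily island-laden replicons
this slightly dilutes the host signal.  Transient intermediate hosts can
never be excluded.

## Fragmentation analysis

Within one genome, islands are linked when their similarity exceeds 80%
and their distances to the host pattern differ by at most 15 points;
islands within 15% of the host pattern are excluded first (amelioration
makes unrelated islands converge on the host signature).  An island
whose removal leaves its neighbours in two or more separate components
is an intermediate and is set aside (reported, not silently dropped).
Groups are the remaining components of size ≥ 2; at most 10 are kept
(larger counts overlap), the rest marked unresolved.  Both group counts
are reported: components of size ≥ 2 only, and origins including
unameliorated singletons — a lone foreign island is plausibly one
acquisition, but the stricter count is available alongside.

## The synthetic generator

Hosts are first-order chains with a strongly biased base composition —
each base frequency in [0.10, 0.45] and a spread of at least 0.15
between the most and least frequent base — and almost no higher-order
structure (transition rows Dirichlet-concentrated at 3000 around the
base composition).  The bias is what real replicons have, and it is load
bearing: it spreads the word spectrum so core windows have stable
rankings (D noise floor: median 8 kb window distance ≈ 17–20), while the
absence of higher-order structure keeps RV at its sampling level and
hence core V ≈ 0.9–1.0.

Donors are log-tilts of the host composition: base frequencies
`host · exp(1.1·u)`, with `u` a unit direction kept near-orthogonal to
the host's own log-composition axis (|cos| ≤ 0.22 — tilts along that
axis amplify the existing ranking instead of reordering it) and
pairwise separated (cos ≤ 0.85), plus per-donor dinucleotide structure
(rows Dirichlet-concentrated at 150).  These knobs were calibrated once,
before the test suite was written, so that at the default thresholds:
implanted 20 kb islands are detected with borders within tens of bp,
10 kb same-donor islands score ≈ 84–92% similarity (above both the 75%
floor and the 80% fragmentation threshold), different donors average
≈ 40%, and independent hosts sit ≥ 30 distance apart for flux tests.
The default corpus is 30 genomes × 300 kb with 10 implanted 10 kb
islands each; donor j occupies island slot j, giving ten 30-member
island families; lineages follow a nested binary taxonomy so every rank
from strain to family is populated.  Amelioration is emulated by point
substitutions drawn from the host base composition.

What the generator does **not** emulate: real gene structure and codon
bias, GC-skew and replication-strand asymmetries, repeats and mobile
elements with internal repeats, rearrangements, circular topology, and
donors whose divergence is purely higher-order (invisible to RV/GRV
separation as constructed).  Passing benchmarks therefore demonstrate
the machinery is correct and calibrated on signals of the modelled kind;
they do not certify sensitivity/specificity on real genomes, where
amelioration, strand asymmetry and compositionally atypical native loci
(e.g. rRNA operons, highly expressed genes) blur the same statistics.

## Numerical and interface choices

* Coordinates: 0-based half-open internally, 1-based inclusive in every
  user-facing file; converters are exact inverses.
* Determinism everywhere: stable sorts with lexicographic tie-breaks in
  rankings, representative choice and cluster ordering; fixed date
  stamps in written GenBank files so corpus regeneration is
  byte-identical from a seed.
* GenBank compound locations are flattened to min..max with strand kept;
  islands are contiguous intervals, exon precision is irrelevant here.
* MCL non-convergence after 200 iterations returns the current partition
  with `converged=False` rather than raising.
* Unknown k-mer sizes: only k = 4 is exposed; the statistics generalise
  but are untested for other k.
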
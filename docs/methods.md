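# Methods

This note documents the models, numerical choices and open design
decisions behind `regmotif`, in the order a ChIP analysis would meet them.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, alphabet, formats

All internal coordinates are 0-based half-open; conversions happen only at
format boundaries (BED is kept verbatim; GFF's 1-based inclusive start/end
map to `start-1`/`end`; WIG's 1-based starts map to `start-1`).  The
working alphabet is {A, C, G, T, N}.  On FASTA import, lowercase is
uppercased, U becomes T, and the other IUPAC ambiguity letters map to N
with a warning (strict mode: error).  N is handled conservatively
everywhere downstream: a pattern symbol never matches a genome N, a
scoring window containing N is skipped rather than scored, and masked
Gibbs sites are written as N so they cannot be re-sampled.

Two text formats are defined by this package because no compact standard
exists at this scale:

* **Motif matrix format** — `>name` (optionally `>name kind=affinity`)
  followed by one line per motif position with 4 values in A C G T order.
  Values are written with 17 significant digits so write-then-read is
  numerically exact.
* **Alignment blocks** — `=block <seq_id> <start> <end>` followed by
  `name<TAB>gapped_sequence` rows, first row = reference.  The degapped
  reference row must equal the genome subsequence (validated on load).
  This deliberately replaces MAF: it preserves exactly the semantics the
  conservation filter needs (a reference span plus gapped orthologous
  rows) and nothing else.

The MEME-minimal reader/writer handles `MOTIF` blocks with
letter-probability matrices; the BioProspector reader accepts a simplified
site-block dialect (`Motif #k` headers, site lines ending in the aligned
word) and builds count matrices from the sites, since that program's
output has no single canonical grammar.

## Interval algebra, gene assignment, peaks

Set operations are **per-base**: the result of union/intersection/
subtraction is the base-membership set reassembled into maximal disjoint
intervals.  Record identity is intentionally not preserved — an overlap
join is a different operation and out of scope.  Strand is ignored unless
stranded mode is requested (then each strand class is processed
separately).

Gene assignment measures the distance from the region's nearest edge to
the gene: overlap means distance 0; otherwise the gap-plus-one in bp to
the gene boundary on the strand-aware upstream (5' of the TSS) or
downstream side, compared against `max_upstream` / `max_downstream`.  With
`allow_multiple=False` only the minimum-distance gene(s) survive, and
exact ties keep all tied genes (divergent promoters are reported for both
flanking genes).

Peak extraction thresholds a numeric track: maximal runs of bases with
value ≥ threshold, runs separated by ≤ `merge_gap` bases merged, merged
runs shorter than `min_width` dropped; the peak value is the run maximum
and the summit is the leftmost base attaining it (leftmost tie-break for
determinism).  This is a refinement utility, not a peak caller: no
background model, no replicates.

## Motif model and scoring

Frequencies are regularized by mixing with the background,
`f' = (1-p) f + p b`, default pseudo-weight `p = 0.01` — strong enough to
keep zero-frequency entries finite, weak enough not to distort
high-information motifs.  Log base 2 throughout (scores and information
content in bits).  The default background is order-0 frequencies of the
bound genome, uniform when none is bound.  Affinity motifs (MatrixREDUCE
style) are normalized to column maximum 1 and scored multiplicatively;
they never pass through the log-odds path.

### Match p-values

The null is a single window of W i.i.d. background draws, one strand;
multiple testing across the windows of a scan is deliberately left to the
caller.  For W ≤ 10 the survival function is exact: all 4^W word scores
and probabilities are enumerated by iterated outer sums.  For larger W (or
when requested) a compound importance sampler draws each word from an
equal-weight mixture of geometrically tilted product proposals
`q_beta(w) ∝ prod_i f'(i,w_i)^beta b(w_i)^(1-beta)` with
`beta ∈ {0, 1/3, 2/3, 1}`.  The `beta=0` component is the defensive
background component (it bounds the importance weights `b/q` by the number
of components); the intermediate temperatures populate mid-to-high score
levels, keeping the relative error of the tail estimate low at stringent
thresholds, which a single fully-tilted component does not.  The reported
standard error is the sample standard deviation of the weighted indicator
over √n.  A two-component version (background + full tilt) was measured as
unbiased but with noticeably higher estimator dispersion at the 99th
percentile; the temperature ladder was adopted for that reason.

### Whole-sequence scores

*Cumulative LOD* is defined here as the positive-part window sum
`Σ max(LOD - floor, 0)` over both strands, floor configurable, default 0
bits — "cumulative" is ambiguous (signed sum vs positive part), and the
positive part is the variant that behaves as an enrichment score rather
than being dominated by the many strongly negative windows.

The *w-score* models the sequence as a concatenation of single background
bases and motif-emitted W-mers: at each step the motif state is entered
with weight `w`, giving the forward recursion
`L(n) = (1-w) b(x_n) L(n-1) + w P_motif(x_{n-W+1..n}) L(n-W)`.
The score is `log2 L(ŵ)/L(0)` with `ŵ` maximizing the likelihood by
bounded scalar search on `log10 w ∈ [-6, log10 0.5]` (tolerance 1e-6), and
is clamped at 0 because `w → 0` recovers the background model.  The HMM is
single-strand (the motif state emits forward-strand W-mers); scan the
reverse complement for the other orientation.

### Conservation filtering

A match is kept when, in the alignment block covering it, at least `k`
non-reference rows contain — after gap removal, within the aligned span
widened by one motif width per side — a window (either strand) scoring at
least `score_fraction` × the reference score.  Matches outside every block
are dropped in strict mode (default) and kept in lenient mode.  The ±W
widening tolerates small alignment slippage without letting a distant
paralogous site rescue a match.

## Gibbs discovery

ZOOPS model: each sequence holds zero or one site; the prior probability
of zero sites is `zoops_prob` (default 0.1 — binding-region sets routinely
contain siteless regions, and the value is configurable because the cited
samplers leave it free).  One *iteration* is one held-out-sequence update,
taken round-robin: the count matrix is built from all other sequences'
sites (with a background-proportional pseudocount totalling 1), and the
held-out sequence's site is re-sampled across all N-free windows on both
strands (configurable) with posterior weight
`(1-γ)/m · prod f'(i,·)/P_bg(window)`, versus `γ` for no site.  The
background probability of a window uses the order-k background (k ≤ 3,
default 0).  Once per sweep the current configuration is scored
(`Σ_sites log2 f'(site)/b(site)`, an information-content-times-sites
measure) and the best configuration seen is reported — the
predictive-update maximum, which is robust to the chain wandering after it
has found the signal.  Restart `r` uses RNG seed `seed + r`; the best
restart wins; reported sites are masked to N before the next motif is
sought.  Phase shifts of ±1-2 bp between the recovered and planted matrix
are an inherent ambiguity of fixed-width samplers; recovery metrics
therefore align matrices over offsets before correlating columns.

## Motif comparison

Each library target is aligned to the query at every offset with
≥ `min_overlap` (default 5) overlapping columns, in both orientations.
Column pairs are scored by Pearson correlation (default) or negative
Euclidean distance between regularized frequency columns; a constant
column (e.g. from an `N` position) gets correlation 0 by convention.  The
per-column null is the distribution of the metric over all column pairs of
the library itself, discretized into 100 bins; the p-value of an alignment
of L columns is the tail mass of the L-fold convolution of that null on
the bin lattice, Bonferroni-multiplied by the number of
offset × orientation configurations tried for that target.  Libraries
smaller than 10 motifs cannot calibrate a null from their own columns; the
fallback for Pearson is the *exact* analytic independence null for 4-point
correlation — density ∝ (1-r²)^((n-4)/2) with n = 4, i.e. uniform on
[-1, 1] — and for Euclidean a seeded Dirichlet(1,1,1,1) column sample.

## Statistics

* **Fisher exact** (enrichment 2×2 tables): two-sided conditional
  hypergeometric, summing the probabilities of all tables no more probable
  than observed, with a 1e-9 relative tolerance for float ties.  Computed
  directly from log-binomials (gammaln) rather than through a generic
  routine so the exhaustive margins ≤ 50 verification stays fast; unit
  tests cross-check it against `scipy.stats.fisher_exact`.
* **Control-free enrichment**: when no control set is given, controls are
  dinucleotide-shuffled copies of the target sequences (Altschul–Erikson
  edge-shuffling, seeded), preserving dinucleotide composition.
* **Positional distribution**: each match is assigned to the nearest
  anchor (geometric interval centers, ties to the leftmost anchor); the
  primary test is a chi-square goodness-of-fit against uniform over 10
  equal bins of the relative position, with a KS test reported alongside.
  Interval centers are taken as `(start+end)/2` — the center of the
  occupied bases — which keeps lattice positions off the bin edges;
  integer-midpoint binning measurably inflates the type-I error through
  systematic boundary misallocation.  Fewer than 10 matches flags the
  result underpowered; fewer than 2 is an error.
* **Spacing**: facing-edge gaps of all ordered same-sequence pairs within
  `max_gap` (self-pairs excluded when the two sets coincide); the observed
  per-gap-window counts are compared against `n_permutations` re-placements
  of the second set uniformly within its sequences (lengths preserved);
  empirical p `(1 + #{null ≥ obs})/(1 + n_perm)` per window, BH-adjusted
  across windows.
* **GO enrichment**: annotations are propagated to all ancestors (cycles
  rejected); for every term with ≥ 1 study gene the hypergeometric upper
  tail is computed and Bonferroni-corrected by the number of tested terms
  (the GO TermFinder convention; BH is reserved for motif-library and
  spacing-window multiplicity).
* **Upstream analyses**: a gene's upstream window is `(TSS - upstream_bp,
  TSS)` strand-aware, truncated at sequence edges and (by default) at
  neighboring gene bodies, keeping the sub-interval touching the TSS —
  the appropriate convention for compact genomes.

## Synthetic data

The fixtures module generates: i.i.d. genomes with controlled GC; planted
motif sites sampled from the frequency matrix (or consensus mode for
deterministic scores) spliced in without overlap, with the truth set
returned; ChIP-like tracks as triangular bumps (height at the site center,
linear decay) plus i.i.d. Gaussian noise; gapless alignment blocks with
i.i.d. substitutions at a set rate, optionally zero inside truth sites;
non-overlapping alternating-strand gene models with a shallow two-level GO
DAG whose first term marks a designated gene subset.  Every generator is a
pure function of its arguments and seed.

What this does *not* emulate — and hence what green tests do not show
about real data: read-level noise and fragment-length effects of actual
ChIP-Seq, sequence composition structure (isochores, repeats, CpG
islands), indels and rearrangements in alignments (gap *parsing* is
covered by hand-written fixtures; simulated rows are gapless so the
conservation tests stay analytic), overlapping gene structures, and
realistic GO DAG depth.  Calibration results (type-I error of the
uniformity and spacing tests) transfer to real data only to the extent
that the null there is genuinely uniform/unstructured.

## Verification problem sizes

The acceptance layer runs, per seed: 20 random PSSMs of width 3-5 against
full 4^W enumeration plus 10^5-sample importance-sampling checks at the
90th/99th-percentile thresholds; a width-6 both-strand scan of a 10 kb
genome (1.2% N) against a per-window scorer; 500 random interval pairs on
a 10 kb universe against boolean masks; 10 Gibbs fixture seeds (20 × 100
bp, one ~16-bit site each, 5 restarts × 2000 iterations); all 2×2 tables
with both sample sizes ≤ 50 (1,755,625 tables) against the scipy
hypergeometric oracle; 1000 uniform-null positional replicates and 100
spacing-null replicates (200 permutations each) at alpha 0.01, plus 20
planted-30-bp-spacing replicates (1000 permutations); the 20/5/5
hypergeometric worked example; all 87,380 sequences of length ≤ 8 against
segmentation enumeration for the HMM forward recursion; fuzzed round-trips
for every format; and conservation retention at substitution rates
{0, 0.1, 0.3} with 30 consensus sites.  The whole script completes in a
few minutes on one CPU.

## Known limitations

Scanning is vectorized per sequence but not chunked: genomes are held in
memory as Python strings (fine for microbial/fungal genomes, the intended
scale).  Exhaustive p-values stop at W = 10 by design.  The Gibbs sampler
is fixed-width, without EM polishing or dyad models.  Motif comparison
calibrates against the supplied library, so E-values across databases of
very different sizes are not comparable beyond the built-in Bonferroni.
Higher-order backgrounds are supported in discovery but the p-value null
is order-0.
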
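# Methods

This note documents the statistical model implemented by `prokmethylome`, the
parameters it exposes, the scope of the synthetic-data generator, numerical
choices, and known limitations. Everything stated here is either a definition
of the implemented procedure or a property verified by the test suite; no
unverified empirical claims are made.

## 1. Data model

Inputs are a genome (FASTA; ambiguity codes other than N are masked to N), an
annotation (GFF3; CDS and `*RNA` features), a per-position, per-strand kinetic
table (CSV: contig, 1-based position, strand, base, ipdRatio, coverage), and a
motif list (TSV: IUPAC pattern, 1-based methylated-base offset, modification
type). Internally coordinates are 0-based half-open; annotations keep their
1-based inclusive convention with explicit accessors.

## 2. Motif scanning

A degenerate pattern is compiled to a regular expression inside a lookahead so
overlapping occurrences are all reported. A genomic N never matches any
pattern symbol. A pattern equal to its IUPAC reverse complement is
palindromic: each site is reported once, carrying the methylated position on
both strands (reverse-strand offset `L - 1 - fwd_offset`). Asymmetric patterns
are scanned on both strands and reported per matching strand. Motif
architecture is classified by a heuristic: an internal run of ≥ 3 N with
specific flanks → Type I bipartite; a double-strand palindrome → Type II;
otherwise ≤ 5 specific positions → Type III-like, ≥ 6 → Type IIG-like.

## 3. Methylation calling

For one palindromic motif:

- `avg_motif` = trimmed mean of ipdR over all methylatable motif positions on
  both strands; `avg_nonmotif` = the same over all same-base positions outside
  motif footprints. Trimming keeps the central 60% of the sorted values
  (floor((1−0.6)/2·n) removed from each end).
- `under_thr = 0.1·avg_motif + 0.9·avg_nonmotif`;
  `meth_thr = 0.5·avg_motif + 0.5·avg_nonmotif`.
- An instance is `low_coverage` unless both strands have coverage ≥ 20 at the
  methylated positions; `unmethylated` if both strand ipdRs are strictly below
  `under_thr`; `methylated` if both are at or above `meth_thr`; otherwise
  `ambiguous`.

The boundary semantics (strict `<` for unmethylated, inclusive `≥` for
methylated, coverage inclusive at 20) are asserted exactly in the tests.

## 4. Enrichment statistics

Regulatory regions run from 100 bp upstream to 50 bp downstream of each CDS
start, strand-aware and clipped to the contig. Unmethylated-vs-methylated
enrichment in a region set is a two-sided Fisher exact test on the 2×2 table
of (state × in/out of regions); fold is the ratio of the two in-region
fractions. Motif-placement enrichment compares the observed in-region fraction
with 1,000 composition-matched resamplings: each motif window is re-placed
uniformly among all N-free windows of identical base composition, and a pooled
Fisher test compares observed against resampled counts. COG-category tests
repeat the Fisher test per category letter (flagged at p < 0.01 when observed
exceeds background); TFBS overlap uses the same machinery at p < 0.05.

## 5. Unmethylated clusters

A cluster is a maximal run of ≥ 3 consecutive unmethylated instances in which
every adjacent gap is strictly smaller than the genome-wide mean inter-motif
distance. Significance: with `l` instances of which `n` are unmethylated,
draw `n` of `l` indices without replacement, re-apply the spatial criterion,
and estimate `p = (1 + successes) / (1 + iterations)` over 10,000 iterations
(Laplace smoothing keeps p > 0). An exact enumeration over all C(l, n)
labellings serves as the oracle for small `l`; the Monte-Carlo estimate is
verified to lie within 3 standard errors of it.

## 6. Non-coding scan and density profiles

Non-coding regions are the complement of merged CDS/RNA intervals. For each
region, the local motif density is estimated from up to 100 flanking
non-coding regions (50 per side, focal region excluded); the observed motif
count is tested against Binomial(region length, density) with upper tail
`P(X ≥ observed)` (a strict-tail variant `P(X > observed)` is available via
configuration), Bonferroni-corrected by the number of regions, significant
below 1e-5. Density profiles count motifs in 500 bp windows at 50 bp steps
across a 50 kb span (991 windows when unclipped). Significant clusters are
matched across genomes when their flanking genes are reciprocal best hits
(directly or strand-flipped).

## 7. Conservation

Homology is scored as `100 · bitscore(hit) / bitscore(self)`; scores ≥ 35
(inclusive) mark potential orthologs. An MTase is conserved within a taxon
when strictly more than half of the taxon's species carry an ortholog.
Reciprocal best hits require mutual unique best scores (ties disqualify).
Orphan-MTase families are built per modification group (m6A vs pooled
m4C/m5C) by complete-linkage agglomerative clustering on 1 − identity, cut so
that every within-family pair shares ≥ 35% identity, then subdivided by
canonical motif (minimum of pattern and reverse complement) and taxon.

## 8. Synthetic-data generator

`build_scenario` produces complete, deterministic input bundles:

- genome: i.i.d. bases at a target GC (default 0.5, 200 kb);
- annotation: non-overlapping CDS (300–1,500 bp) spread over the whole genome
  with multinomially distributed intergenic gaps; COG letters cycle through
  {K, T, H, E, J};
- methylome: the genome is edited until it carries exactly the requested
  number of motif instances; a configurable subset is marked unmethylated,
  biased toward regulatory regions (default 60%); the `ori_cluster` preset
  plants 20 extra instances evenly through one 600 bp intergenic gap;
- kinetics: coverage per strand is Poisson (mean 60), independent of state;
  ipdR is lognormal with median 4.0 at methylated m6A positions (3.0 m4C,
  1.5 m5C) and 1.0 elsewhere.

**Deliberate deviation.** The lognormal scale at a position is
`sigma / sqrt(coverage)` with `sigma = 0.25`, modelling the ipdR as a
per-position *average* over reads whose uncertainty shrinks with coverage.
A coverage-independent position-level `sigma = 0.25` would make the
both-strands-strict unmethylated rule fail its own ≥ 0.95 sensitivity
requirement (the probability that two independent lognormal(0, 0.25) draws
both fall below the under-threshold is ≈ 0.73), i.e. the generator and the
caller would be mutually inconsistent. The chosen model preserves the stated
medians, the sigma → 0 limit, and the m5C < m4C < m6A detectability ordering.

## 9. Numerical choices

- Fisher exact p-values come from `scipy.stats.fisher_exact` (two-sided) and
  are verified against direct hypergeometric point-mass summation on **all**
  2×2 tables with total ≤ 50 (tolerance 1e-10).
- Binomial tails use `scipy.stats.binom.sf(k−1, n, p)` and are verified
  against pmf summation.
- Permutation draws use `numpy.random.default_rng` with explicit seeds;
  without-replacement index draws are vectorised via `argpartition` on
  uniform noise, and iteration batches are chunked to bound memory.
- Trimmed means sort once and slice; thresholds and calls are exactly
  reproducible for fixed inputs.

## 10. Limitations

- Calling is defined for palindromic (double-strand) motifs; asymmetric
  motifs are scanned and reported but not state-called.
- The kinetic model is a two-level lognormal with state-independent coverage;
  it contains no sequence-context effects, no partial methylation fractions,
  and no strand asymmetries.
- The conservation module consumes externally computed bitscore/identity
  tables; no alignment is performed in-package.
- The non-coding scan's binomial null treats positions as independent; motif
  self-overlap makes it slightly conservative for short regions.
- Single-contig genomes are assumed by the pipeline driver (the first FASTA
  record is analysed); the library primitives themselves are contig-aware.
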
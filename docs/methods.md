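# Methods

## Model and assumptions

The package treats EST counts as a proxy for isoform expression: with
non-normalized cDNA libraries and sufficient depth, the number of ESTs
supporting an isoform is approximately proportional to its expression.
Each EST is a single contiguous read aligned to one reference transcript
as ordered exon blocks; the gaps between blocks are putative introns.
Strand is ignored — ESTs and MRE catalogs are assumed oriented to the
mRNA sense strand of a UniGene-style per-gene reference.

Relative to a specified MRE interval, an EST is informative only when its
aligned footprint covers the entire MRE. Informative ESTs are
MRE-containing (MRE inside one exon block) or MRE-free (MRE inside one
gap, or split across a junction — a partial site is presumed
non-functional and counted free). A deliberate reading choice: the
configuration catalogue's "exon" case is implemented as *presence* of the
MRE in an exon, which is the only reading consistent with the worked
contingency example and with the containing/free interpretation of the
classes. The catch-all class (v) is reserved for alignments that violate
structural assumptions (unsorted/overlapping blocks) detected at
classification time; like class (i) it never enters any count.

### Fisher exact test

For tissue *t*, the 2×2 table holds MRE-free/MRE-containing counts in *t*
(a, b) and in all other tissues (c, d). The test statistic is *a*; with
margins fixed, X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b).
Orienting the statistic on the MRE-**free** count fixes the tails so that
a significant left P (P(X ≤ a)) means the tissue is enriched for
MRE-containing isoforms and a significant right P means enrichment of
MRE-free isoforms. The two-tailed P uses the minimum-likelihood rule —
the sum of P(X = k) over all k with P(X = k) ≤ P(X = a)·(1 + 1e-7), the
tolerance factor guarding against floating-point ties. Probabilities are
computed in log-space from log-gamma, so tables of any realistic size are
exact to floating precision; degenerate margins return P = 1 on all three
tails.

Thresholds: tests run only for genes with ≥ 10 informative ESTs and, per
tissue, only when a + b ≥ 10. The threshold is applied to *informative*
ESTs (the stricter reading; excluded ESTs say nothing about the site). An
MRE is called splicing-regulated when any tested tissue/stratum reaches
two-tailed P < α (default 0.05); the direction is reported from the
one-tailed Ps. No multiple-testing correction is applied across tissues
or sites — the method is deliberately a per-site screen. Histology
stratification (normal vs cancer libraries analysed separately) is off by
default.

When a catalog is summarized, rows sharing one (reference, interval) —
one element bound by several microRNAs — collapse to a single unique site
before the regulated fraction is computed.

### Region merging and repressiveness

Pairwise overlap between sites is |intersection| / min(|a|, |b|); the
shorter-site denominator makes containment count as complete overlap,
which is what groups many co-located microRNA sites into one region.
Pairs at ≥ 0.90 are merged by single-linkage transitive closure. Both the
denominator and the transitivity are design decisions — "at least 90 %
overlap" does not by itself fix either — and are stated here so results
are reproducible. A region is highly repressive when the *maximum* member
repressive ratio is ≥ 30 % (inclusive: a single-member region at exactly
30 qualifies). Regions whose members carry no ratio yield an
"unavailable" summary rather than an error.

The bundled VEGF catalog (`splicemre/data/vegf_mre_catalog.tsv`) is a
literature-curated table of 30 microRNA sites with repressive ratios
measured in hypoxia-induced CNE cells; one member ratio (the miR-302d
site at 1935–1955) is printed inconsistently in its source (40 in the
per-microRNA list vs 30 in the range column) — the per-microRNA value is
used; the region is highly repressive under either.

### Random-MRE null

Random MREs are drawn as coordinates on the real references — source,
start, then length uniform in 18–22 nt (truncated at the region end) —
rather than as free sequences, so they are directly testable without a
re-matching step. Sources are sampled uniformly among references long
enough to hold the minimum length; in 3′UTR mode only annotated
sub-intervals are used. Each set's regulated fraction runs through the
identical enrichment machinery; sets with no testable site become missing
values with a logged warning. The observed catalog fraction is compared
with the set fractions by a one-sample Wilcoxon signed-rank test,
two-sided (random fractions are not normal, hence a rank test). Exact
P-values come from the full sign-assignment distribution (computed by
convolution over the doubled ranks, identical to enumerating all 2^n sign
vectors) up to n = 25 nonzero differences; beyond that a tie-corrected
normal approximation with continuity correction is used. Zero differences
are dropped; ties receive average ranks.

### Protein-level shifts

Log2 fold changes map to the percent-change axis by (2^lfc − 1)·100, the
standard reading of SILAC expression ratios; repression is negative.
Proteins partition into seed-free vs seed-carrying sets, with nested
predicted-target and alternatively-spliced subsets (nesting is validated
and violations rejected). Cumulative curves are plain ECDFs. The
two-sample KS statistic D is the supremum ECDF distance over pooled
points; its P-value uses the asymptotic Kolmogorov series with the
small-sample effective-size correction λ = (√ne + 0.12 + 0.11/√ne)·D.
The exact small-sample KS distribution is out of scope; a brute-force
oracle for D covers the statistic in tests, and the planted-shift
simulations give the series plenty of signal. Sets are compared against
the seed-free baseline, with medians reported so the shift direction is
explicit.

## Synthetic data: what it emulates and what it does not

Each synthetic gene is a random-sequence reference (default 2,000 nt)
with one 200-nt cassette exon at [900, 1100) carrying a 21-nt MRE at
[975, 996). Default tissues are brain, colon, lung and liver (the classic
EST-example panel), each with 2 libraries and 30 ESTs, all normal
histology; the default inclusion probability is 0.5 everywhere. ESTs are
sampled as footprint windows (default 300–800 nt) uniform on the chosen
isoform, so uninformative configuration-(i) ESTs arise naturally.
"Regulated" sites are planted by per-tissue inclusion overrides and
recorded in the ground truth.

Known caveat: with partial windows the probability that an informative
EST covers the MRE differs slightly between including and skipping
isoforms (covering an exon-internal interval vs straddling a junction),
so retention measured among informative ESTs is mildly biased relative to
the nominal inclusion probability. The bias is identical across tissues,
so null Fisher tables remain null; the retention-convergence test uses
full-isoform windows (window bounds 1800–2000), where the estimate is
unbiased and every EST is informative. Simulations that need exact
informative counts (type-I, power) use the same full-isoform windows.

The generator does not model sequencing error, EST chimerism, 3′-end
read bias, library-size differences, or alternative
cleavage/polyadenylation. Passing tests therefore demonstrate
correctness of the statistical machinery under clean isoform sampling,
not robustness to those artefacts of real dbEST data.

Protein tables draw background lfc ~ Normal(0, σ²) with σ = 0.3 by
default; seed-carrying records are shifted by −δ_seed and the spliced
subset by a further −δ_as (defaults 0.5 each), mirroring the expected
ordering of repression across the nested sets.

## Simulation sizes used by tests and the acceptance script

* Type-I error: 500 null genes × 4 tissues × 15 informative ESTs =
  2,000 tissue tables; rejection at α = 0.05 checked against
  0.05 + 2·√(0.05·0.95/2000). Fisher is conservative on discrete tables,
  so observed rates sit near 0.03.
* Power: 200 replicates of a planted site (inclusion 0.9 focal vs 0.1
  background, 30 informative ESTs per side); recovery is required in
  ≥ 95 % of replicates, and a co-simulated homogeneous site must stay at
  the null call rate.
* Random-null comparison: 6 genes (3 planted), 20 random sets × 20 sites.
* Protein shifts: sets of 600/200/120/60 with δ_seed = δ_as = 0.5,
  σ = 0.3; all three KS comparisons reach P < 0.001.
* The exhaustive Fisher oracle covers every 2×2 table with N ≤ 40 in
  exact integer arithmetic (≈ 1.3 × 10⁵ tables).

## Numerical and degenerate-input choices

* Intervals are 0-based half-open internally and 1-based inclusive in all
  TSV I/O; BED12 keeps its native convention. An MRE abutting a block
  boundary is contained, not straddling.
* Sequences are normalized U→T, upper-case; `N` is accepted in references
  but never matches in exact or seed search.
* P-values are clamped to (0, 1]; result TSVs print floats with six
  significant digits.
* Ties in `merge_regions` ordering are broken by (start, end, site_id);
  region indices are 1..K by ascending start.
* `wilcoxon_one_sample` raises when every difference is zero (the test is
  undefined); `fraction_regulated` raises on an empty catalog or when no
  site is testable.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; there is no global RNG state, and identical
  config + seed reproduce outputs byte-for-byte.

## Known limitations

* Exact-match placement only: no gapped or mismatched alignment of MRE
  sequences (sites that differ from the reference by even one base will
  not be placed).
* Seed matching implements the 7-mer complement of microRNA nt 2–8 only;
  A1/8-mer variants are out of scope.
* The asymptotic KS P-value is anticonservative for very small samples;
  comparisons with n < ~25 per side should rely on the D statistic.
* The per-site screen applies no multiple-testing correction; genome-wide
  use should treat calls as candidates, which the random-MRE null is
  designed to calibrate.
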
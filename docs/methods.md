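# Methods

This note documents the models implemented in `pavpop`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Presence calling and the PAV matrix

A gene is called present in a library from its aggregated alignment
summary (percent identity, percent coverage, number of distinct contigs
carrying its exons). Two boundary semantics coexist deliberately: the
single-contig clause is strict (identity and coverage **>** threshold)
while the split-alignment clause is inclusive (**≥**, on 2–3 contigs).
Two presets are shipped: `within_genus` (85 single / 90 split) for
congeneric gene sets and `cross_genus` (70 identity, 75 coverage
single / 80 split) for divergent outgroups. Because these boundaries
change genome-wide counts, they are exposed as a `PresenceRule` rather
than hard-coded. Presence calling is monotone: raising identity or
coverage can only turn absent into present.

Libraries with fewer than 39,000 present genes are excluded before any
occupancy statistics — low counts indicate assembly failure, not
biology. Whether coverage is measured against transcript or CDS length
is the caller's responsibility; the rule only consumes the numbers it
is given.

## Occupancy classification (core / shell / cloud)

Per-gene occupancy (fraction of retained libraries containing the gene)
is clustered with 1-D k-means at k = 1..6, 20 seeded restarts each, and
the within-cluster-sum-of-squares BIC

    BIC(k) = n · ln(WSS_k / n) + k · ln(n)

is recorded for every k. On continuous occupancy data this curve
decreases for all k — splitting any cluster with nonzero spread reduces
the first term by O(n), which dwarfs the ln(n) penalty — so its
arg-min is uninformative (it always sits at k_max). We therefore select
k\* at the **elbow** of the BIC curve, the k maximising the
second-order difference BIC(k−1) − 2·BIC(k) + BIC(k+1), which is how
successive-k-means BIC traces are read in practice. Two consequences
are documented rather than hidden:

* data whose one-cluster fit is already essentially exact (WSS/n below
  1e−10, e.g. an all-ones occupancy vector) short-circuit to k\* = 1,
  since an elbow is undefined there;
* the elbow rule cannot distinguish one loose cluster from two; it is
  intended for occupancy vectors with genuinely distinct classes.

On planted data (Beta-distributed occupancies around 98% / 56% / 12%,
302 libraries, ≥ 1,000 genes per class) the rule recovers k\* = g for
g ∈ {1, 2, 3} and cluster means within ±3 percentage points. Clusters
are always relabelled by descending mean occupancy, so `core` is the
top cluster regardless of k-means label permutation.

## Subpopulation enrichment

For each gene, observed presence counts o_i across s subpopulations are
compared with e_i = O·n_i/N (O = Σo_i; n_i subpopulation sizes, N their
sum; admixed samples excluded beforehand). χ² = Σ(o_i−e_i)²/e_i with
df = s−1; for the four-subpopulation design the α = 0.05 critical value
is 7.81. Genes with O = 0 are excluded (their expected counts would be
zero) rather than assigned χ² = 0. p-values come from the χ²
distribution and are Benjamini–Hochberg corrected across all tested
genes. The test's null is multinomial allocation of a gene's
occurrences across subpopulations; when presence is instead simulated
independently per library, counts are hypergeometric-like and the test
is conservative — the test suite uses the multinomial null for its
type-I-error check for exactly this reason.

Private genes: frequency strictly > 0.1 inside one subpopulation and
exactly 0 elsewhere by default; the strict-absence tolerance is a
parameter (`max_other_freq`) because "specific to" admits degrees.

## Selection statistics

Per-site π = 2·c₁·c₀/(n(n−1)) over non-missing alleles; window π is the
sum over SNPs divided by window length (windows 0-based half-open;
monomorphic sites contribute nothing). Tajima's D follows the standard
coefficients (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂); D is undefined at S = 0
and reported as null. D is computed in 10-kb non-overlapping windows by
default, and the lower 1% of windows are flagged as sweep candidates.

EHH among carriers of a core allele is the probability that two random
carriers are identical from the core to the current marker,
Σ C(e_h,2)/C(n_c,2). iHH integrates EHH over physical distance
(trapezoid, both directions), truncated at the first marker where EHH
drops below 0.05 — hapbin's default cutoff, and physical distance
because genetic maps are unavailable for such panels. Sites whose EHH
reaches a chromosome edge before the cutoff are skipped, not
extrapolated. Unstandardized iHS = ln(iHH_ancestral/iHH_derived);
standardization subtracts the mean and divides by the SD within
derived-allele-frequency bins (50 equal-width bins, bins with < 20
records merged left-to-right), making |iHS| > 2 comparable across
frequencies. Window scans report the fraction of |iHS| > 2 SNPs per
100-kb window sliding by 10 kb; windows with fewer than 10 scored SNPs
(configurable) are null. Outlier calling takes the extreme 1% by
default — mirroring the Tajima rule, since "highest fraction" fixes no
number — and includes ties at the cut.

## Coalescent bottleneck test

The simulator is a single-locus (no recombination) Kingman coalescent
under a piecewise-constant size history, with time in units of 4·N₀
generations. Waiting times are drawn at rate C(k,2) in rescaled time
and mapped through the inverse cumulative coalescent intensity of the
size function (piecewise linear, so inversion is an interpolation).
Mutations are Poisson(θ/2 · total branch length); each mutation's
subtended leaf count i is drawn from the classical branch-size
distribution P(i|k) = C(n−i−1, k−2)/C(n−1, k−1), contributing
2·i·(n−i)/(n(n−1)) to π. This reproduces E[S] = θa₁, E[π] = θ,
Var[S] = a₁θ + a₂θ², and matches msprime's moments in the cross-check
test.

Defaults for the domestication null model (none are fixed by the
motivating data, so all are configuration): N₀ = 100,000 with one
generation per year; bottleneck starting 8,000 years ago
(t = 0.02 coalescent units) with duration half its age; n = 40
haplotypes per population; per-window θ = 4·N₀·μ·L with
μ = 6.5×10⁻⁹/bp/yr, i.e. θ = 52 for a 20-kb window. The two populations
are simulated independently — the test compares diversity levels only,
so shared ancestry is a deliberate simplification of a split model.

Severity f is calibrated by bisection (in log f, since f spans orders
of magnitude) of the paired mean ratio mean(π_bottleneck)/
mean(π_constant) against the target (default tolerance 0.01); paired
replicates share random draws, which makes the simulated ratio monotone
in f and cancels most genealogical noise from the ratio. An
unattainable target raises an error reporting the attainable range.
The sweep test reports the add-one empirical
p = (1 + #{ratio ≤ observed})/(kept + 1) over per-replicate ratios,
discarding (and counting) replicates with π_constant = 0. Without
recombination a 20-kb window shares one genealogy, so the null ratio
distribution is wide; the resulting p-values are calibrated (uniform
under the null) but conservative relative to a recombining window —
a stated limitation, and the reason no particular published p-value is
a target of this implementation.

## LD decay

r² is the squared Pearson correlation of dosages over
pairwise-complete samples (undefined for monomorphic sites). Thinning
keeps one SNP per 100 bp greedily left to right; pruning removes the
later SNP of any within-window pair with r² > 0.5 (window/step 50
SNPs), a deterministic stand-in for plink's victim choice, which is not
specified by its documentation. Profiles average r² in left-closed
100-bp distance bins for pairs within 500 SNPs and 2 Mb. The default
decay model is the Hill & Weir (1988) expectation of r² with the single
parameter c (recombination scale per bp) and fixed sample size n,
fitted by pair-count-weighted least squares; a hyperbolic fallback
a/(1+bd) is available and recorded in the fit object. The decay extent
is the smallest distance where the fitted curve reaches 0.2, found by
root bracketing; a flat profile or a curve that never reaches the
threshold is an error, not a number.

## TE burst and insertion dating

K2P: K = −½·ln(1−2P−Q) − ¼·ln(1−2Q) with transitions P and
transversions Q over ungapped, unambiguous columns (excluded pairwise,
not listwise); non-positive log arguments raise a saturation error and
become missing entries in distance matrices. Ages divide by 2μ because
divergence accrues on both lineages — for copy pairs since the burst,
and for the two LTRs of one element since its insertion (LTRs are
identical at insertion time). The burst report gives the mean and
min–max range over copy pairs, both of which are meaningful: the mean
estimates the burst age, the range its spread. With ~2 expected
substitutions per 6.5-kb copy at 45,000 years, a single 12-copy family
dates the burst with ~20% Monte-Carlo error; experiments that need a
tighter estimate average replicate families, as the acceptance script
does.

Insertion presence is called from read pairs mapped to the
insertion-bearing reference: a pair supports a junction when one read
lies entirely outside and its mate entirely inside the element;
`present` needs ≥ 2 supporting pairs at *both* junctions (resisting
single chimeric pairs), `absent` needs zero junction support and ≥ 2
pairs bridging the empty site, anything else is `ambiguous`.

## Annotation name mapping

Normalized identity = identical aligned residues / length of the longer
sequence, from a deterministic global alignment (BLOSUM62, gap open
−10, extend −0.5 for proteins; +2/−1 with −5/−2 gaps for nucleotide
sequences). The original procedure used BLASTP local alignments; global
alignment is aligner-free and deterministic at the scale this package
targets, and for the near-full-length matches the rules require, the
two agree closely. Mutual best hits break exact score ties toward the
lexicographically smaller id (logged). Locus names carry forward on a
unique same-strand overlap (≥ 1 bp, coordinates supplied by the caller)
plus an MBH protein pair at ≥ 0.70; transcript names need ≥ 0.90,
either as a protein MBH or via the transcript-MBH rescue for models
differing mainly in UTR. "Similarity" and "identity" are conflated in
common usage; this package uses normalized identity throughout. Name
mapping is injective, and mapping an annotation against itself maps
everything to itself.

## Synthetic data: what it does and does not emulate

* **PAV generator** — Beta-Bernoulli occupancy (concentration 200 by
  default) gives tight unimodal classes like real occupancy clusters
  and avoids degenerate all-0/all-1 columns; presence is independent
  across libraries, so it carries no population structure or linkage
  between genes. Enrichment power on structured data is therefore
  tested with explicitly constructed matrices, not this generator.
* **TE generator** — one ancestor, independent Poisson substitution
  counts per copy, transitions:transversions κ:1 per event (κ = 2
  default, so K2P is the matched estimator); no indels, no gene
  conversion between LTRs.
* **Sweep generator** — a planted *hard* sweep: carriers share one
  identical haplotype across the swept width, the background is
  independent sites. This validates EHH/iHS mechanics and window
  calling, not the subtler signals of soft or incomplete sweeps with
  recombination.
* **LD generator** — a template-copying process with switch probability
  1−exp(−ρd) between adjacent sites and a 1% copying error; it yields
  monotone distance-decaying r² but is not a coalescent with
  recombination, so absolute r² levels are not calibrated to any
  demography.
* **Read-pair generator** — pairs are placed deterministically on
  alternating junctions (or across the empty site) with uniform jitter;
  no mapping errors or chimeras.

Passing tests on these generators shows the estimators recover planted
truth under their matched assumptions; it does not certify behaviour on
real data with structure, linkage, or alignment artefacts.

## Problem sizes and numerical choices

The recovery experiments use 15,000 genes × 302 libraries for
classification, 40 replicate 12-copy families for burst dating, and
12,000 paired replicates for bottleneck calibration followed by 1,000
fresh 20-kb windows — sizes at which each experiment's Monte-Carlo
error is comfortably inside its stated tolerance. Floating-point
guards: WSS is floored at 1e−12 inside the BIC; the branch-size CDF
sampler clips the drawn leaf count at its support edge; empirical
p-values are add-one to avoid zero. All randomness flows through
explicit `numpy.random.default_rng(seed)` generators; no global state.

## Known limitations

* The elbow-based k selection needs at least two genuine clusters or
  near-degenerate data; arbitrary k_max changes beyond 6 are untested.
* No recombination in the coalescent (single shared genealogy per
  window) — conservative sweep p-values, as discussed above.
* iHS integration uses physical distance; recombination-map support is
  out of scope.
* The LD profile loop is quadratic in SNPs per window; it targets
  thinned desk-scale panels, not genome-scale marker sets.
* Name mapping assumes both annotations share one coordinate frame;
  cross-assembly liftover is the caller's job.
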
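# Methods

`hapassort` re-implements, as a tested pipeline, the population-genetic
analyses used to evaluate claimed habitat assortment between two deeply
diverged mitochondrial lineages of the slippery dick wrasse
(*Halichoeres bivittatus*) in the Florida Keys: lineage assignment of
cytochrome-*b* haplotypes, haplotype networks, pairwise Nei Fst between
habitat types and sites with a fixed-sample-size permutation null, and
single-threshold GMYC species delimitation with a likelihood-ratio
test.  A structured-coalescent generator produces synthetic datasets
with the study's sampling design so that every stage can be verified
without external data.

## Units and the generative model

All times and branch lengths are expressed in **expected substitutions
per site**.  This avoids committing to an absolute clock and makes the
divergence time and diversity parameters compose additively into
expected distances:

- `theta` — within-lineage diversity: pairwise coalescence rate is
  `2/theta`, so the expected pairwise distance within a lineage is
  `theta`.  Default 0.005 (0.5%), a typical intraspecific mtDNA scale.
- `tau` — lineage divergence time.  Default 0.0225, chosen so the net
  between-lineage divergence `2*tau + theta = 0.05` matches the ~5%
  split reported for this system (the observed p-distance is slightly
  lower, ~4.85%, because of finite-sites saturation).
- `theta_anc` — ancestral diversity, default `theta`.
- `alpha` — lineage-habitat assortment in [0, 1].  An individual is
  northern with probability `(1 + alpha)/2` in inshore habitats
  (inshore patch reef, grass bed), `(1 - alpha)/2` on offshore reef,
  and 1/2 elsewhere.  The default is `alpha = 0` (random placement),
  matching the study's empirical finding; `alpha = 1` encodes the
  ecological-speciation hypothesis of complete segregation.
- `L` — fragment length, default 723 bp (the cytochrome-*b* fragment).

Simulation proceeds in three conditional stages: lineage labels are
drawn per individual given habitat; a Kingman coalescent runs within
each lineage until `tau`, when survivors merge into one ancestral pool
with rate `2/theta_anc`; finite-sites Jukes–Cantor mutations are then
dropped on the genealogy (Poisson(`L` × branch length) per branch,
uniform site, uniform different base).  Finite sites (rather than
infinite sites) was chosen deliberately so that saturation behaves like
the distance models assume downstream.

The default site design is 8 Keys sites summing to 78 samples: four
offshore-reef sites (14, 9, 4, 16), two inshore patch reefs (12, 10),
and two grass beds (12, 1).  The sizes 4 (offshore "xmuta") and 1
(grass-bed "kml") reproduce the 4-vs-1 site comparison that motivates
the exhaustive permutation mode; the remaining six sizes are package
defaults chosen uneven, since per-site counts for the original design
are not published in machine-readable form.

What the generator does **not** emulate: among-site rate variation and
codon structure (mutations are iid JC69), transition/transversion bias
(so TN93 ≈ JC69 on simulated data — this is exploited as a nesting
test, but means simulated data cannot probe TN93's advantages),
alignment gaps and ambiguity codes, migration after divergence, and
non-clocklike rate variation.  Passing calibration on simulated data
therefore validates the statistical machinery under the stated model,
not robustness to these real-data features.

## Distances

`p` (uncorrected), `jc69`, and `tn93` with pairwise deletion: columns
containing a gap, `N`, or an IUPAC ambiguity code in either sequence
are excluded for that pair.  TN93 uses the observed A↔G and C↔T
transition proportions, the transversion proportion, and base
frequencies averaged over the two sequences; the implementation agrees
with `ape::dist.dna(model = "TN93")` to 12 decimals when ape is given
the same per-pair frequencies.  Saturated or undefined corrections are
returned as `+inf` with a flag (TN93 additionally falls back to JC69
with a warning when a base-frequency class is empty), never as silent
NaN.  The divergence headline is reported under both `p` and `tn93`
because the ~5% figure in the literature does not name its model.

## Clock tree

UPGMA (average linkage; node height = half the merged-cluster mean
distance) stands in for a Bayesian strict-clock phylogeny.  For two
clades separated by a gap that dwarfs within-clade diversity the root
split is the same, and the construction is fully deterministic: ties
are broken by the lexicographically smallest pair of cluster
representative ids.  Externally inferred clock trees (e.g. an MCC tree)
can be supplied as Newick; ultrametricity is validated to a relative
tolerance of 1e-6 of tree height, and polytomies are resolved by
zero-length splits in sorted-label order.

Lineage assignment takes the two subtrees of the UPGMA root; labels
are oriented by user anchors when given (for simulated data the
pipeline anchors on the recorded truth of one sample per lineage),
otherwise "northern" is the group containing the smallest sample id,
and the policy used is recorded in the output.

The haplotype network is a minimum spanning tree over distinct
sequences under mismatch-count distance (Kruskal, ties by weight then
id pair).  MST was chosen over statistical parsimony as the minimal
defensible construction; the choice is recorded in report metadata.

## Pairwise Nei Fst and the permutation null

The mitochondrial fragment is one non-recombining locus; alleles are
whole haplotypes (default) or the two lineage classes.  For groups with
allele frequencies `p_k` and sizes `n_k`:

    h_k  = 1 - sum_i p_ki^2           (x n_k/(n_k - 1) when all n_k >= 2)
    Hs   = (h_1 + h_2)/2
    Ht   = 1 - sum_i pbar_i^2 + Hs/(2*ntilde)
    Fst  = 1 - Hs/Ht                  (0 when Ht = 0)

with `pbar` the per-allele mean of the two frequency vectors and
`ntilde` the harmonic mean sample size.  The estimator variant is
pinned and recorded in output: the sample-size bias correction is
applied only when **every** group has at least two samples; when a
group is a singleton (for which the corrected form is undefined) the
plug-in diversities are used for both groups, keeping the two sides of
the comparison on the same convention.  Slightly negative estimates
for identical polymorphic groups are expected under the unbiased form.

Significance uses the study's scheme: samples are reshuffled between
the two groups with sizes fixed.  When the number of distinct
assignments `C(n1+n2, n1)` is at most 100,000 the null is enumerated
exhaustively and `p = #{Fst_perm >= Fst_obs}/total`; otherwise
Monte-Carlo with the add-one convention `p = (1 + hits)/(1 + n_perm)`,
which is never zero and conservatively valid.  The test is one-sided
(large Fst).  Pairs are tested pairwise (matching "between all pairs"),
raw p-values are reported, and a Holm adjustment is available behind a
flag; the calibration harness reports the family-wise rate both ways.
A monomorphic pooled pair returns p = 1 with a flag.

Measured calibration at the default design (alpha = 0, 200 replicates,
199 permutations): the raw any-pair rate over the three habitat pairs
is ~0.13–0.14, consistent with the Šidák-composed nominal rate
1 − 0.95³ = 0.143; the Holm-adjusted family-wise rate stays at or
below 0.05.  Power at alpha = 1 with the default divergence is ~1.

## Single-threshold GMYC

A threshold height `T` on an ultrametric tree separates diversification
(Yule) events above from within-cluster coalescences below; each
lineage crossing `T` roots one coalescent cluster.  Between successive
events the total branching rate is

    b_i = lambda1 * n_i^p1 + lambda2 * sum_j [n_ij (n_ij - 1)]^p2

with `n_i` the diversification lineage count (zero below the
threshold) and `n_ij` the lineage count of cluster `j`.  Each interval
contributes `b_i * exp(-b_i * x_i)` — survival times the total rate,
the canonical single-threshold form; the series runs from the present
to the root and no survival beyond the root is modelled.  Intervals
lie wholly above or below the threshold, so the likelihood separates
into the two components, and for fixed exponents each rate MLE is
closed-form (`lambda_hat = E / sum(term * x)` with `E` that
component's event count).  Fitting therefore profiles the rates
analytically and performs two bounded one-dimensional searches over
the exponents (range [0, 3], deterministic 7-point grid then Brent;
rates clipped to [1e-4, 1e4]).  On simulated single-population
coalescent trees the fitted null exponent centers on its true value
(median 0.999 over 100 replicates), and the profile optimum matches a
brute-force four-parameter quasi-Newton search to 1e-6.

Candidate thresholds are the interior node heights (deduplicated at
1e-12, strictly positive) plus the root height, whose fit *is* the
single-coalescent null — including it makes the likelihood-ratio
statistic `2(logL - logL0)` nonnegative by construction.  Ties break
toward the root (fewer clusters).  The LRT p-value uses a chi-squared
reference with df = 3 by default (threshold + extra rate + extra
exponent); df = 2 is exposed.

Identical sequences produce zero-length branches whose zero-duration
coalescent intervals degenerate the rate fit, so the pipeline's
delimitation stage runs on one representative per haplotype — the
standard practice for this method.

**Measured operating characteristics** (all by simulation, reported by
`scripts/acceptance.py`):

- *Power.* Recovery of two clades (n = 25 per clade) as exactly two
  entities with LRT p ≤ 0.05 depends sharply on the ratio of the
  between-clade gap to the within-clade depth: ~0.4 at ratios 10–20,
  ~0.9 at 80, ~0.98 at 150 (the calibration regime used here:
  tau = 0.3, theta = 0.002).  Notably, the study system's own regime
  (2·tau/theta ≈ 9–18) sits in the weak-power zone, which is
  consistent with a non-significant GMYC test despite ~5% divergence.
- *Type-I error.* On panmictic coalescent trees (n = 40) the LRT at
  nominal 0.05 rejects in ~12–23% of replicates (≈0.18 pooled over
  400).  The inflation is structural: the alternative maximizes over
  ~n−1 candidate thresholds while the chi-squared reference does not
  account for that selection.  The LRT should be read as approximate
  and anticonservative; entity counts and the threshold height are the
  more interpretable outputs.

## Numerical choices and degenerate inputs

- Ultrametricity tolerance 1e-6 (relative); Newick round-trips
  preserve heights to 1e-9.
- UPGMA requires finite distances and fails loudly on a saturated
  matrix.
- Fst permutation ties count as exceedances at tolerance 1e-12.
- GMYC needs ≥ 3 leaves (≥ 3 haplotypes in the pipeline); a 2-sample
  dataset degrades to frequencies and network only, with notices.
- All randomness flows from `numpy.random.default_rng(seed)`; reports
  are byte-identical across runs with the same inputs and seed.

## Problem sizes

Calibration runs use the default 78-sample design with 199
permutations and 200/60 replicates (type-I/power), 50 two-clade
replicates at n = 50, and 100 panmictic replicates at n = 40; the
synthetic benchmark stand-in has 133 samples.  These sizes give
binomial standard errors of 2–5 percentage points on the reported
rates while keeping a full calibration run under a few minutes on one
core.

## Known limitations

- The UPGMA stand-in assumes clocklike data; strongly rate-varying
  data should come with a user-supplied clock tree.
- GMYC delimitation on distance-based trees of closely related
  haplotypes tends to oversplit (it reports many shallow entities on
  the two-lineage stand-in); the LRT's anticonservatism compounds
  this.  Conclusions about species limits should lean on the entity
  structure and threshold depth, not the bare p-value.
- The permutation test conditions on observed haplotype frequencies;
  with singleton sites its exhaustive null is extremely coarse
  (5 distinct outcomes for 4-vs-1), so "significant" results at such
  sizes are artifacts of granularity — the motivating example of the
  original analysis.
- TN93 on short fragments with skewed composition can be undefined;
  the JC69 fallback is flagged, not hidden.
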
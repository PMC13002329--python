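# Methods

This note records the models and procedures implemented in `dosagebal`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that affect results.

## Dosage-balance statistics

The central object is a per-species copy-number table with columns
`asmt`, `comt`, `total` (and optionally `receptor`), where
`asmt + comt = total` by construction. Two OLS fits, ASMT ~ total and
COMT ~ total, summarize how copy-number growth is partitioned between the
subfamilies. Because the responses sum to the regressor, the slope
estimates satisfy β_ASMT + β_COMT = 1 to machine precision on *any* input —
this algebraic identity is asserted as a property test rather than a
statistical claim. The slope ratio β_ASMT/β_COMT is the headline contrast
(binomial allocation with share p yields expected slopes p and 1−p, hence
ratio p/(1−p); share 0.6 gives 1.5). The proportion-vs-total trend is
reported as both Pearson r and Spearman ρ since either may be quoted for
such a fit; on degenerate inputs (constant share or fewer than three
species with nonzero totals) the trend is NaN rather than an error.

High/low-copy groups come from one-dimensional k-means with k = 2. Centers
initialize at the minimum and maximum and Lloyd iterations run to a fixed
point; in one dimension with k = 2 this is a deterministic threshold rule
on the sorted totals (verified as a property test), so no seed is involved.
Group contrasts use Welch's unequal-variance t-test and the two-sided
Mann–Whitney U test with tie correction; Welch was preferred over the
pooled-variance t-test because high- and low-copy groups have no reason to
share a variance. The group statistic defaults to the COMT proportion;
either share can be selected.

Cross-ploidy comparison reports the fold change of mean totals plus the
same two tests on totals and on a subfamily share. Fold changes are
exposed at full precision with a 2-dp convenience property, since published
values are conventionally printed to two decimals.

The expression contrast pools per-gene FPKM values by subfamily, drops
values < 1 (below that level FPKM is dominated by mapping noise), removes
outliers by Tukey fences at 1.5×IQR per subfamily (configurable, `"none"`
disables), and compares the pools by Mann–Whitney U with a direction flag
on the medians. Outlier removal is applied per subfamily so that one
highly expressed subfamily cannot define the other's fences.

## Pan-genome clustering and openness

`greedy_cluster` mirrors CD-HIT's greedy incremental semantics: sequences
sorted by length descending (ties broken by id, making output
reproducible), each joining the *first* cluster whose representative it
matches, else seeding a new cluster; the seed — the longest member — stays
representative. A `best_match` option switches to best-identity
assignment. Identity and coverage are computed from a global BLOSUM62
alignment (gap open −10, extend −0.5): identity = identical positions /
gapless aligned columns; coverage = gapless aligned columns / shorter
sequence length (modes `longer` and `query` available). CD-HIT's own
short-word heuristics are not reproduced — at the scale this package
targets (hundreds to thousands of family proteins, not whole proteomes)
exact global alignment is affordable and better defined.

Occupancy classes follow the standard pan-genome partition: Core (present
in 100% of varieties), Shell [90%, 100%), SoftCore [10%, 90%), Cloud
(< 10%); Dispensable = everything not Core. Class boundaries are
half-open so the four classes partition exactly.

The openness curve is estimated by sampling-without-replacement: each of
`n_iter = 100` iterations permutes the varieties uniformly and counts, at
each step N, the OGGs first observed in the N-th variety; the curve is the
per-N mean. On a 3-variety matrix this equals the exhaustive average over
all 6 permutations (tested). The power law n = k·N^−a is fit by nonlinear
least squares *on the original scale* (log-log fits weight small-N points
incorrectly), initialized from the log-log linear regression; pseudo-R² is
1 − SSres/SStot on the original scale. N = 1 is included by default
(`min_n` excludes early points); nonpositive curve values are dropped with
a warning. Noiseless curves round-trip (k, a) to well beyond 6 significant
digits.

## Ka/Ks and Ks-peak dating

The concrete estimator is Nei–Gojobori (1986) — a counting method is
transparent, exactly testable against enumeration, and adequate for
within-family comparisons at moderate divergence. Site counts per codon
come from per-position degeneracy with stop-creating changes counted as
nonsynonymous, so S + N = 3 per codon exactly. Observed differences in
multi-hit codons are averaged over all substitution orderings with equal
weight, excluding pathways through stop codons (with a guard falling back
to all pathways if every one is blocked). Proportions pS = Sd/S and
pN = Nd/N are corrected by Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p);
p ≥ 3/4 flags the pair as saturated (a reason code, not an exception), and
Ks = 0 flags the ratio undefined rather than infinite — such pairs must be
excluded from mean-Ka/Ks summaries, which is how finite published means
arise. Coverage is complete codon pairs over the codon count of the
shorter ungapped CDS; pairs under 75% coverage are dropped before Ks-peak
fitting.

Ks distributions are decomposed with 1-D Gaussian mixtures fit by EM
(scikit-learn backend: 10 k-means-initialized restarts, tolerance 1e-6,
max 500 iterations, variance floor 1e-6) for k = 1..6, selecting the k
that minimizes BIC = −2·logL + (3k−1)·ln(n). The *global peak* — the
argmax of the fitted mixture density on a 2001-point uniform grid over the
data range — is reported separately from the component means, because a
quoted "Ks peak" (e.g. 0.338) is the mixture mode while the nearest
component mean (0.339) is a model parameter; the two differ when
components overlap. Divergence dates use T = Ks/(2·r)×10⁻⁶ Myr with the
plant nuclear rate r = 6.5 × 10⁻⁹ substitutions/site/year (configurable).

## Catalog stage

Candidate family members need a passing hit (E ≤ 1e-5) from either the
domain scan or the similarity search — the union rule maximizes recall
when two complementary searches were run; `require_both` gives the
conservative intersection. Protein length must lie in the closed interval
[200, 600] aa (shorter risks domain loss, longer suggests annotation
fusion). Filtering is idempotent.

Subfamily labels come from the best global-alignment score against labeled
ASMT/COMT references, ties broken by identity then by lexicographically
smaller reference id, making the result independent of reference order.
Phylogeny-based arbitration is out of scope.

Divergence-driving alignment columns are ranked by the mutual information
(plug-in estimate, bits) between residue identity — gaps as a 21st
symbol — and the subfamily label, with a label-permutation null for
per-column p-values. MI was chosen over wrapped tree-ensemble importances
because it is a *defined* statistic: invariant to residue relabeling and
class swaps (tested), bounded by H(label), and exactly 0 for constant
columns. `top_k` defaults to 13, the size of the diagnostic-residue set
this family is known for; indices are 1-based and alignment-relative.

## Synteny stage

Anchors carry gene-order ranks per chromosome (from GFF3 start order).
Chains are found per chromosome pair by O(n²) dynamic programming over
anchors sorted by rank, requiring strictly monotone ranks in both genomes
(increasing, or decreasing for inverted chains) and per-step gaps
≤ `max_gap` = 25 ranks; chains shorter than `min_size` = 5 anchors are
discarded — both defaults mirror common MCScanX practice and are
configurable. Blocks are peeled greedily (best chain reported, anchors
removed, repeat), which resolves overlapping anchors to their best chain.
Chain score is anchor count by default (`bits` weights by score); unit
weights keep results reproducible without alignment scores.

Duplication classes are assigned in strict priority: block anchor →
wgd_segmental; rank-adjacent family member on the same chromosome →
tandem; within 10 ranks → proximal; any family member in the same
genome → dispersed; else singleton. The synteny network has one edge per
distinct anchored family pair; communities are connected components —
deterministic and dependency-free, with label propagation as an optional
alternative — rather than a modularity heuristic.

## Synthetic-data generators

The generators define the study conditions; they are pure functions of
spec + seed (bit-identical reruns, tested).

- **Copy tables**: totals uniform on [2, 120] (spanning the observed
  spread of family sizes from low-copy eudicots to high-copy grasses),
  ASMT ~ Binomial(total, share), COMT the remainder. Binomial allocation
  is the natural null for "each copy is ASMT with probability p" and
  forces the slopes-sum-to-one identity. Receptor counts, when enabled,
  are Poisson around a low mean (~2 copies) with an optional weak
  dependence on the total.
- **Codon pairs**: differences are planted at distinct codons at observed
  proportions p = (3/4)(1 − e^(−4d/3)) per site class, classified exactly
  from the ancestor, so the NG86/JC estimator inverts to the targets in
  expectation. At most one change per codon keeps classification exact;
  the cost is a capacity limit (planted changes must fit the sequence),
  which is the practical form of the saturation bound. No indels, no
  GC-content matching, no rate heterogeneity.
- **Pan-genomes**: independent random ancestors per OGG (background
  identity ~5%, far under the clustering threshold), per-variety copies
  mutated to 98% identity, dispensable presence i.i.d. Bernoulli.
  Dispensable OGGs that draw zero varieties stay in the truth matrix so
  occupancy-mean recovery is unbiased; they emit no sequences.
- **Ks mixtures**: untruncated Gaussian draws (negative Ks allowed) so
  component-mean recovery is unbiased; truncation would shift recovered
  means upward relative to the generating parameters.
- **Labeled alignments**: shared per-column residue distributions with
  planted class-specific residues (the first diagnostic column uses W/F,
  the known key ASMT/COMT site) and configurable leakage.
- **Expression**: log-normal FPKM with a COMT log-scale shift.

Because generators draw i.i.d. across species/varieties/genes, passing
recovery tests demonstrate estimator correctness under the stated noise
models — not robustness to phylogenetic non-independence, annotation
error, alignment uncertainty, or expression batch effects, all of which
real data add.

## Problem sizes and numerical choices

Test and acceptance computations use the analysis-scale inputs the methods
are specified at where that is cheap (1052 species for regressions, 10,000
Ks draws for mixture refits, N = 1..48 openness curves) and reduced sizes
where an oracle is exhaustive (≤ 3-codon NG86 enumeration, 3-variety
openness permutations, ≤ 12-anchor chain enumeration). Mixture refits of
overlapping components recover means to about ±0.02 at n = 10,000; the
two better-separated recoveries are tested at that tolerance and the BIC
is expected to pick the true component count only at ≥ 4 sd separation.
EM non-convergence within the iteration cap on overfit k values is
tolerated (the BIC comparison stands); a non-finite lower bound is an
error. The power-law fit can fail on closed pan-genomes (fewer than three
positive curve points); the pipeline records a null fit in that case.

## Known limitations

- NG86 assumes equal base frequencies and no transition/transversion or
  codon-usage bias; for deep divergences a ML codon model would differ.
- Greedy first-match clustering is order-dependent by design (the order is
  fixed and documented); borderline sequences near the identity threshold
  can join a different cluster than a best-match strategy would choose.
- The k-means split assumes two latent copy-number regimes; truly
  unimodal totals still get partitioned.
- Connected components merge communities that a modularity criterion
  would separate when sparse bridges exist between dense clusters.
- The 1-D mixture BIC tends to underfit heavily overlapping components;
  reported component counts are conditional on the selected k.
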
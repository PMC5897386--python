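# Methods

## The analysis in one paragraph

Two halves of a replicated environmental gradient (sites 1–4 = Section 1,
sites 5–8 = Section 2, three replicates per site) each yield a signed OTU
co-occurrence network; the networks are aligned by a mixture of 16S sequence
identity and graphlet topology; the OTU sets are decomposed into core
(in both networks) and noncore, and rule-based functional profiles are
contrasted between these sets. The package implements every stage plus a
synthetic-community generator that plants known structure so each stage can
be validated by recovery rather than by eyeballing.

## Network inference

**Measures.** Pearson and Spearman correlations are computed on
relative-abundance profiles; Bray–Curtis on per-OTU normalized profiles
(each OTU's relative abundances rescaled to sum to one across the section's
samples, so the measure compares profile *shape*, not magnitude);
Kullback–Leibler is symmetrised, `0.5·[KL(p‖q) + KL(q‖p)]`, on
+1-pseudocounted profiles because raw KL is undefined at zeros and
asymmetric. Abiotic variables enter as z-scored rows; pairs involving a
variable are scored with the two correlation measures only, since
dissimilarities of signed z-scores are not meaningful.

**Candidate selection.** OTU rows occurring in fewer than `minocc = 10`
samples are removed (after the 2-of-3 replicate filter and the 5-sample
occurrence filter). Each measure ranks all eligible pairs; a pair becomes a
candidate when it is in every applicable measure's strongest `n_pos = 1000`
co-presence or `n_neg = 1000` exclusion selections and its Pearson and
Spearman signs agree with the tag. Selection is invariant to row and sample
order.

**Edge testing.** The permutation null shuffles one member's relative
abundances across samples, regenerates its counts binomially at each
sample's sequencing depth, then restores the compositional totals
(`total − x + x_permuted` becomes the new denominator for both members)
before recomputing the measure. Regenerating counts at the destination
sample's depth matters: with sequencing depths spanning 3,900–26,000 reads,
raw-count shuffling moves low-depth (noisy) values into high-depth samples
and the null then underestimates the variance of the observed score — in
our calibration experiments that inflated the 5% rejection rate on
association-free pairs to ~30%, while the depth-matched null restores it to
3–7%. The p-value is the two-sided Gaussian tail of the observed z against
the null sample (an empirical-rank option exists behind a flag); n = 1000
draws by default. The bootstrap resamples samples with replacement; a
measure is discarded ("killed") when the permutation-null mean falls inside
its bootstrap 95% interval, and an edge survives only if at least one
measure does.

**Merging.** Per-edge measure p-values are merged with Brown's method
(Fisher's statistic with an empirical covariance correction estimated
across edges; plain Fisher when fewer than ten edges share a measure set),
then Benjamini–Hochberg across edges at q < 0.05. By default only nodes
incident to a retained edge appear in the network; a flag keeps all
filtered-surviving OTUs as isolated nodes instead.

**Statistics.** Clustering coefficient is the mean local transitivity
(0 for degree < 2); characteristic path length averages shortest paths over
reachable pairs; density is `2E/(N(N−1))`; heterogeneity is
`sd(degree)/mean(degree)`. The degree-distribution verdict fits a
zero-truncated Poisson and a discrete power law (xmin = 1, zeta-normalised)
by maximum likelihood to degrees ≥ 1 and applies a sign test to the
per-node log-likelihood differences; |normalized statistic| < 2, or fewer
than 30 nodes, is inconclusive. The sign test was chosen over the
variance-normalized ratio because a single high-degree node dominates the
variance term and made the variance-normalized version indecisive on
unambiguous heavy-tailed inputs.

**Randomization.** The edge-shuffling null performs as many moves as there
are edges; each move re-draws one random edge between two random nodes
other than its current endpoints, rejecting self-loops and duplicates, so
node set and edge count are conserved exactly.

## Graphlets and alignment

Orbit counts for graphlets on 2–4 nodes (15 orbits; orbit 0 is the degree)
are computed by per-edge accumulation with boolean vectors, which is
algebraically equivalent to enumerating every connected induced subgraph —
a brute-force enumerator over node subsets serves as the independent oracle
in the tests. Graphlets on 5 nodes (73 orbits) are available behind
`max_graphlet=5` via ESU enumeration; their orbit numbering follows this
package's canonical ordering (by size, edge count, degree sequence), which
reproduces the conventional numbering for orbits 0–14.

Signature similarity between two orbit vectors `u, v` is
`1 − Σᵢ wᵢ·|log(uᵢ+1) − log(vᵢ+1)| / log(max(uᵢ,vᵢ)+2) / Σᵢ wᵢ` with unit
weights. Node score is `alpha·seqsim + (1−alpha)·toposim`; **alpha weights
sequence identity** (alpha = 1 sequence-only, alpha = 0 topology-only).
Variable nodes use name identity as their "sequence" similarity and only
align to variable nodes.

The optimizer is greedy seed-and-extend: a lazy priority queue over node
pairs keyed by node score plus `edge_bonus = 0.5` per already-aligned
neighbour pair the candidate would conserve; ties break lexicographically
on the id pair, which makes the algorithm deterministic and makes
self-alignment return the identity mapping (an identity pair's bonus always
weakly dominates its competitors'). EC and SS are computed with the
smaller-edge-set network as source. The consensus alpha of a scan is the
grid point maximising the harmonic mean of EC and SS (ties toward smaller
alpha) — a tie-break construction of this package, since only the outcome
of such a scan, not a rule, is conventionally reported.

## Core/noncore and functions

Core = OTU nodes present in both networks (variables excluded). Hubs are
nodes whose degree exceeds the network's 90th degree percentile (strictly
above, so a star's centre is its only hub); abundant means mean relative
abundance > 0.1%; environment-correlated per variable means Spearman
p < 0.05 and |rho| at or above the 90th percentile of significant values.
Function rules are exact taxon matches at a stated rank
(greengenes-prefixed); a ~30-rule trimmed FAPROTAX-style table ships as
package data and full tables load through the same TSV schema. A group's
per-site category share sums the relative abundance of its labelled OTUs;
the default denominator is whole-sample abundance (shares of disjoint sets
then add), with a per-set denominator option under which the community value
is a weighted mixture of its subgroups' values. Group comparisons use
one-way ANOVA (≥ 3 groups) or the two-sample t-test, p-values uncorrected.

## The synthetic generator

Gradient: every variable follows a linear site trend (pH 8.8 → 5.7,
temperature 13 → 4 °C, humidity 20 → 70%, Fe/P/Zn/C/Cu rising, K/Ca
falling, N-derivatives/Mg/S/Na flat) plus measurement noise of 5% of the
range. Within a section all trending variables are therefore affine in the
site index, and their standardized trends are ±collinear — deliberately so,
because it makes the set of "genuinely co-varying" pairs exactly derivable.

Community: OTU log-abundance = log-normal baseline + loading-weighted sum of
latent factors + dispersion noise; counts are multinomial at a per-sample
depth drawn uniformly from 3,900–26,000 reads, so compositional coupling is
really present. Factors are built orthonormal within each section (factor 0
pinned to the standardized pH trend), which makes the noise-free correlation
of two OTUs equal the cosine of their loading rows. Planted truth has two
tiers: **strong** edges (|cosine| ≥ 0.55 — in practice ≥ 0.85 by
construction) are what inference is scored against; **structural** edges
(any shared factor) additionally include the weak minor-factor markers of
role-swap OTUs and define the noiseless networks used in alignment
experiments. Core OTUs load one factor each (alternating signs, group sizes
distinct so factor groups are topologically distinguishable); each role-swap
pair shares a unique factor combination — a dominant main factor
(weight 0.92 of the loading norm, cosine ≈ 0.92 with its group: strongly
recoverable) plus weak minors (cosine ≈ 0.39: below the detection boundary,
but enough to make every swap pattern topologically unique in the structural
networks). The most dominant OTUs are gradient-insensitive generalists with
no loadings; this both concentrates abundance (the top 50 OTUs hold 50–75%
of reads at the default 600-OTU scale) and keeps every planted edge on OTUs
abundant enough to pass the occurrence filters. Sequence identities are
drawn from taxonomy bands (same genus 0.97–0.995, same phylum 0.85–0.93,
else 0.75–0.83); role-swap partners get distinct taxonomy. Nitrogen-fixer
genera are planted in 20% of core OTUs and a ten-fold smaller fraction of
noncore and generalist OTUs.

Defaults emulate the full study design (600 OTUs, 230 core, 80 swap pairs);
`desk_scale_config` is the reduced strong-effect setting used for recovery
experiments (150 OTUs, 85 core, 20 swap pairs, 10 factors, dispersion 0.1,
loading scale 1.1) — small enough that a complete inference of one section
takes a couple of seconds on one CPU, which sets the problem sizes used in
the test suite and acceptance script (10 desk-scale runs for recovery
medians, 500 pairs × 200 permutations for calibration, 20 randomizations
per alignment comparison). The generator uses 10 latent factors rather than
more because the 12 samples of a section can host at most 11 mutually
orthogonal factors besides the constant.

**What passing these tests does and does not show.** The generator
reproduces the design (sites/replicates/sections/depths), compositionality,
dominance, and the core/role-swap logic, but its associations are linear in
log-abundance, its factors are orthogonal, and its taxonomy is synthetic;
real communities have nonlinear responses, correlated drivers beyond a
single gradient axis, and far noisier sequence–taxonomy relations. Recovery
scores here are therefore upper bounds of a sanity-check kind, not field
performance estimates.

## Numerical choices and degenerate inputs

Constant profiles make correlations undefined: such pairs are excluded from
candidacy, and `env_correlation` returns NaN (flagged, never coerced to 0).
Zero-total samples are an error naming the sample. Degenerate permutation
draws are dropped (NaN-aware null moments; p = 1 if fewer than 10 valid
draws). An empty network is allowed with a warning; EC is undefined (None)
for an empty source edge set. All stage seeds derive from a master seed and
the stage name, so identical configs give byte-identical reports and stages
can be re-run in isolation.

## Known limitations

- The four-measure consensus with top-1000 thresholds is conservative by
  construction; associations outside every measure's top lists are
  invisible regardless of significance.
- With 12 samples per section the permutation z of even a perfect
  correlation is ≈ 3.3, so per-edge p-values bottom out near 10⁻³ and FDR
  control at 5% keeps a visible tail of strong-by-chance null pairs
  (precision ≈ 0.9 in recovery experiments).
- The greedy aligner is a deterministic heuristic: scores are comparable
  between runs of this package but not numerically with other global
  network aligners, whose optimizers differ.
- The "phyla-node enrichment" of networks sometimes reported alongside this
  analysis style is not implemented; its construction is under-specified.
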
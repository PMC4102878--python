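# Methods

`cooccurnet` analyzes microbial co-occurrence at three scales: whole
communities (do ecosystems differ in their co-occurrence structure?),
groups of taxa within communities (which taxa form modules?), and taxon
pairs and nodes (which pairs co-occur consistently, and which taxa are
keystones?). This note records the statistical model at each scale, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions.

## Data model

A study is a taxon-by-sample matrix of non-negative integer counts with a
two-level sampling hierarchy: samples belong to replicate groups, replicate
groups belong to ecosystems. Replicates are treated as independent
realizations of an ecosystem's community; every consensus rule and the
mixed model's random factor rest on that interpretation. A replicate label
belongs to exactly one ecosystem (labels are validated, not trusted).

Rarefaction standardizes unequal sequencing effort by drawing, per sample,
a uniform subsample of reads without replacement (multivariate
hypergeometric) down to a user-chosen depth; samples below the depth are
dropped and reported, and dropping may not empty a replicate group. Depth
has no default because it is a property of the dataset, not of the method.
A single seeded draw is performed (no averaging over repeated
rarefactions). Note that subsampling to a fixed depth *closes* each sample
to a constant sum; on data that are otherwise complete observations this
closure induces weak negative dependence between taxa (measured on the
signal preset: the mean Spearman correlation of unrelated pairs shifts
from ~0.00 to about −0.18). Rarefy because depths are unequal, not by
habit; the `demo` pipeline therefore subsamples only when a depth is
requested.

## Community scale: Spearman distance + PERMANOVA

Co-occurrence between two taxa is Spearman's rank correlation of their
abundances across samples (average ranks for ties; two-sided p from the
t approximation, adequate at the tens-of-samples scale this tool targets).
The community-scale distance matrix uses *taxon profiles* as objects: one
object per (taxon, ecosystem, replicate), its profile the taxon's
abundance vector over that replicate's samples, and distance
`d = 1 − rho` in [0, 2] — small distance means strong positive
co-occurrence. Profiles from different replicates are aligned by
within-replicate sample position, which requires a balanced design
(subsample unbalanced data first). Grouping objects by ecosystem turns
"do ecosystems share co-occurrence structure?" into a one-way PERMANOVA:

    SS_total  = (1/N) Σ_{i<j} d_ij²
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d_ij²
    pseudo-F  = [SS_between/(a−1)] / [SS_within/(N−a)]

with significance from random relabeling of whole objects
(default 9999 permutations; p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is
never 0 and ties count against the null). Objects from different
replicates of the same ecosystem are independent draws, so their expected
distance is 1, the same as between ecosystems; the test gains power only
from pairs whose correlation is consistent *within* replicates — exactly
the structure the consensus rule targets. An exhaustive-enumeration mode
(`permanova_exact`) exists for small N and is verified against brute force
over all relabelings; the pseudo-F is verified against an independent
Gower-centering computation to 1e-10.

Alternative object constructions (e.g., one object per taxon-ecosystem
over concatenated replicate samples) are conceivable; the choice here is
isolated in `spearman_distance_matrix` and can be swapped without touching
the test itself.

The composition-level contrast uses classical Bray–Curtis dissimilarity
between samples, optionally after min–max scaling of each taxon row to
[0, 1] so abundant and rare taxa weigh equally, through the same PERMANOVA.

The association measure is pluggable in principle (any statistic mappable
to a [0, 2] distance would do); Spearman is the only measure shipped.

## Within ecosystems: consensus networks and modules

Per replicate, every taxon pair with non-zero abundance rows gets a
correlation; pairs with a constant vector have undefined rank correlation
and are excluded (logged). Edges pass a stringency cutoff — positive
edges `rho > c`, negative edges `rho ≤ −c`, defaults c ∈ {0.5, 0.75}. The
asymmetry (strict positive, inclusive negative) is deliberate and
configurable (`inclusive=True` makes both bounds inclusive). Positive and
negative co-occurrence are separate networks: a sign-mixed module has no
coherent ecological reading.

The consensus network of an ecosystem keeps an edge only if it passes the
cutoff in **every** replicate; each edge records the highest level it
passes everywhere and its weakest correlation magnitude across replicates
(`min_abs_rho`). Consensus is intentionally conservative — it is the
tool's main defense against spurious correlations, and it is monotone:
adding a replicate can only remove edges. Edge p-values are carried in the
correlation tables for reporting but play no role in network construction;
with heavily unequal sample sizes between replicates, p-based cutoffs
would encode sample size rather than effect size.

Modules are found divisively: repeatedly compute shortest-path edge
betweenness (Brandes accumulation, fractional credit over tied shortest
paths, unweighted edges) on the remaining graph, remove the single
highest-betweenness edge (ties broken by lexicographically smallest edge),
and record the component partition after each removal. The returned
partition maximizes Newman–Girvan modularity Q = Σ_c (e_cc − a_c²)
evaluated against the original edge set; Q ties go to the partition with
fewer modules. Everything is deterministic, and every module is connected
in the original network by construction.

## Node scale: statistics, the power model, keystones

Per node: normalized degree `deg/(n−1)` (the divisor the standard graph
libraries use — the maximum possible degree) and unnormalized
shortest-path betweenness with endpoints excluded. Per network: global
transitivity (3 × triangles / connected triples) compared with the
Erdős–Rényi expectation mean-degree/n; a network whose transitivity
exceeds that expectation is flagged small-world in the Watts–Strogatz
sense.

The degree–betweenness relationship is modeled as a power function
`betweenness = α · degree_norm^β`, fit on the log–log scale as a linear
mixed model with a Gaussian random intercept per replicate — the
observations are nodes of *per-replicate* thresholded networks, so
replicate is the natural grouping factor. Nodes with zero degree or zero
betweenness carry no information on the log scale and are excluded rather
than pseudo-counted (pseudo-counts bias β); the exclusion count is always
reported. β's significance is a Wald test on the linearized model. With a
single replicate, or when the mixed optimizer fails on degenerate
(zero-variance) input, the fit falls back to ordinary least squares with a
logged warning; when the replicate variance is estimated at the zero
boundary the intercept deviations are reported as zero.

Keystone taxa are the k taxa with the highest betweenness *predicted* by
the fixed effects α·x^β, using each taxon's mean normalized degree across
replicates; ties break by observed betweenness, then name. Predictions
use fixed effects only — a keystone claim should not depend on which
replicate a taxon happened to be measured in. For β > 0 the ranking is a
monotone transform of degree, so it is invariant to the scale of
betweenness.

Recovery properties (all exercised by the test suite): noiseless power-law
data is recovered to 1e-6; β = 1.5 with log-normal noise σ = 0.3 and
replicate intercepts ±0.2 over 60 nodes is recovered within ±0.3 in
≥ 95/100 runs; under β = 0 the Wald test rejects at ~5%.

## The simulator

`simulate_study` draws replicated multi-ecosystem count tables with exact
control of pairwise rank correlation via a Gaussian copula: latent normal
vectors with correlation `2·sin(π·ρ_target/6)` — the exact inverse of
Spearman's rho for bivariate normals — are pushed through the
negative-binomial quantile function. Margins default to mean 100 with
variance ≈ 5 × mean (size = 25), overdispersion typical of amplicon
counts. Discretization to counts attenuates the realized Spearman slightly;
the attenuation is measured (target 0.8 realized within ±0.05 at n = 1000)
rather than corrected. Correlation structure is per ecosystem and shared
by all of its replicates; draws are independent across replicates; the
target matrix is checked for positive semi-definiteness and rejected with
the offending pairs named. The copula changes dependence only, so
correlated and uncorrelated taxa have identical marginal distributions —
a property the tests verify by KS comparison.

Two presets define the canonical cases, both 2 ecosystems × 3 replicates
× 100 samples × 20 taxa:

* **null** — all taxa mutually independent everywhere. Within-ecosystem
  correlations are then no stronger than cross-ecosystem ones and the
  community-scale PERMANOVA must reject only at its nominal rate (checked:
  rejection rate at α = 0.05 over 200 runs inside [0.01, 0.10]).
* **signal** — the 20 taxa sit on a 5 × 4 grid; in E1 each *row* of 4 is
  fully pairwise correlated at target Spearman 0.85 (30 pairs), in E2 each
  *column* of 5 is (40 pairs). Any two taxa share a row or a column but
  never both, so the ecosystems share no correlated pair.

The signal preset was calibrated deliberately, and the shape of the
calibration is worth recording. With two groups the PERMANOVA has one
numerator degree of freedom, so the permutation distribution of F is wide
(chi-square-like); a handful of strong pairs shifts F far too little to
reject reliably. At the other extreme, one large correlated block per
ecosystem concentrates the dependence into a single latent factor per
replicate, and chance alignment of factors across ecosystems occasionally
collapses the between-group contrast entirely. Many small *independent*
blocks at a sample size that pins down each correlation (n = 100,
sd(null rho) ≈ 0.1) avoid both failure modes: across 50 seeds the signal
preset rejects at the permutation floor every time, which is the regime
the "strong, replicate-consistent correlations" scenario describes.

What the simulator does **not** emulate: compositional (sum-constrained)
counts, sequencing-read noise, unequal depths, unbalanced designs,
phylogenetic correlation of margins, or rare-taxon sparsity. Passing tests
on simulated data therefore demonstrate correctness of the machinery and
calibration of the tests under the stated model, not performance on real
amplicon data — real data add closure effects, depth variation and far
weaker, noisier correlation structure (on the datasets that motivated this
framework, the community-scale test did not reject).

## Problem sizes and runtime choices

The null-calibration operation defaults to 999 permutations per run;
at α = 0.05 a 1/1000 p-resolution is ample, and 200 pipeline runs complete
in well under a minute. Single headline tests use 9999 permutations. The
planted-partition check for module detection uses two 8-node blocks
(p_in = 0.9, p_out = 0.05, 20 seeds) and requires exact recovery in ≥ 18;
betweenness is cross-checked against explicit path enumeration on graphs
of ≤ 12 nodes, where enumeration is exact and fast.

## Known limitations

* One-way PERMANOVA only: replicate structure is not modeled as a nested
  stratum, and permutations are unrestricted. Strongly unbalanced designs
  deserve caution.
* The balanced-design requirement of the community-scale matrix is a real
  restriction; subsample to balance before testing.
* Spearman is the only shipped association measure; compositionally aware
  measures (e.g., log-ratio based) are out of scope.
* The consensus rule's all-replicates requirement is strict by design;
  with many replicates it may be too strict, and a distribution-based
  criterion would be the natural relaxation.
* Girvan–Newman is O(V·E²)-ish per network; the consensus networks this
  tool produces are small (tens of nodes), which is the regime it is
  meant for.
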
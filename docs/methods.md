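# Methods

This note documents the models, estimators, numerical choices and known
limitations of `minkpop`. It is written for users deciding whether the
package's behaviour matches their intended analysis, and for maintainers
auditing the implementation.

## Coalescent scenario simulator

`simulate.DemographicScenario` is an ordered backward-time event schedule
over the sampled populations. Three event types exist:

- **split(t, derived → ancestor)** — at time *t* (generations before
  sampling) every lineage of the derived deme moves into the ancestral deme;
- **admixture(t, derived → (A, B, r))** — each lineage of the derived deme
  independently joins source A with probability *r*, else source B;
- **size_change(t, pop, N)** — the deme's effective size changes to *N*.

Between events, lineages within a deme of (diploid) size *N* coalesce at
rate C(k,2)/(2N) per generation for autosomal loci; mtDNA uses the female
effective size N_f = N/2. Schedules are validated at construction: after the
final event exactly one deme remains, so non-coalescence is impossible by
construction. Times are generations; the package equates one generation with
one year for calendar conversion, following the biology of the focal
species.

Microsatellites mutate under the generalized stepwise model: mutation counts
are Poisson on branch lengths with per-locus rate μ, step sizes are
geometric with parameter p_GSM (p_GSM = 0 reduces to the strict SMM), step
direction is symmetric, and repeat counts reflect at the boundaries of
[5, 60] repeats. Bounded ranges are biologically standard and keep
allele-size-variance statistics (R_ST, (δμ)²) finite. mtDNA uses
infinite-sites placement on L sites (default 476); per-site rate defaults to
7.25×10⁻⁸/site/year, i.e. half of a 14.5 %/Myr pairwise divergence rate.
Infinite sites is appropriate because observed control-region haplotypes in
this study design differ by single steps; finite-sites substitution models
(HKY etc.) are deliberately out of scope.

The hot loops (tree building, mutation dropping, summary statistics) are
numba-compiled kernels with a pure-Python fallback; every kernel call is
seeded explicitly, so all outputs are reproducible from a single integer
seed.

### The fourteen colonization scenarios

`mink_scenarios()` encodes fourteen histories of four sampled populations
(NE, SE, FR, SP) descending from one ancestral deme. Scenarios 1–6 contain
an admixture pulse founding the western lineage: scenarios 1/3/5 without
prior NE–SE differentiation (the NE/SE split coincides with the admixture
time T2), 2/4/6 with differentiation at an older T3; in 1–2 the pulse founds
the FR lineage (SP splits from it at T1), in 3–4 the SP lineage, and in 5–6
FR and SP remain effectively one western deme (encoded as a split one
generation before sampling). Scenarios 7–14 are pure three-step divergence
histories: the four "chain" topologies in which the second western deme
splits from the first, and the four "independent" derivations of FR and SP
directly from NE and/or SE. The source study describes scenarios 7–14 only
qualitatively; this eight-fold enumeration (4 chains + 4 independent
derivations, with FR preceding SP in the independent cases) is this
package's documented interpretation of "all ordered bifurcation orders".

### Priors

Detailed prior bounds were not published with the study, so the package
ships DIYABC-conventional defaults, all overridable through `PriorSpec`:
effective sizes N ~ U[100, 30 000] diploids; event times U[10, 10⁵]
generations with T1 ≤ T2 ≤ T3 enforced by resampling; admixture proportion
r ~ U[0.1, 0.9]; microsatellite rate μ ~ log-U[10⁻⁴, 10⁻³] per locus per
generation; p_GSM ~ U[0, 0.3]. These wide ranges mean a typical prior draw
is considerably more polymorphic than the real species data; that is
intentional for ABC (the prior must cover the data) but worth remembering
when reading synthetic summary tables.

`generate_mink_like()` reproduces the study's sampling layout exactly:
107 + 44 + 73 + 89 = 313 genotyped individuals at 11 loci and 157 mtDNA
sequences apportioned proportionally (54/22/37/44) by largest remainder.

## Diversity and neutrality

Haplotype diversity is Nei's unbiased ĥ = n(1 − Σp²)/(n − 1) with Nei's
sampling variance; nucleotide diversity is mean pairwise differences per
site, with the total (sampling + evolutionary) variance of Tajima/Nei for
its SD. Columns containing `-` or `N` are excluded from all site-based
computations; `trim_gapped_columns` implements the study's rule of dropping
gapped positions before analysis.

Tajima's D uses the standard a₁…e₂ constants. Fu's Fs is
ln(S′/(1 − S′)) with S′ = P(K ≥ K_obs | θ̂_π, n) under the Ewens sampling
formula, θ̂_π taken as mean pairwise differences; the tail probability is
evaluated exactly from unsigned Stirling numbers of the first kind in log
space (cached per n), equivalently the Poisson-binomial representation
K = Σ Bernoulli(θ/(θ+i−1)). One observed haplotype gives S′ = 1 exactly and
is reported as a +∞ sentinel; all undefined statistics carry an explicit
reason, never a silent drop. R2 is √(Σ(Uᵢ − S/2)²/n)/S with Uᵢ the
singleton mutations carried by sequence i.

Significance is simulated: replicates of a constant-size coalescent with n
tips and exactly S mutations placed uniformly on branch length (the
"fixed-S" convention of the classic desktop tools; a θ-conditioned null
would also be defensible but the fixed-S form avoids the nuisance
parameter). D and R2 are tested two-tailed, Fs one-tailed toward negative
values; empirical p-values use the (c+1)/(R+1) correction. Because the null
conditions on S while data arise with random S, the test is approximate; the
acceptance suite measures its actual type-I error at the 5 % level over 500
null datasets and finds it within binomial bounds (≈ 0.04 for all three
statistics at n = 25).

## Microsatellite statistics

Per-population summaries report total alleles N_A, private alleles relative
to the full dataset, allelic diversity A as the plain mean alleles/locus
(not rarefied richness — the arithmetic the study's tables use), observed
heterozygosity, and Nei's unbiased expected heterozygosity
(2n/(2n−1))(1 − Σp²) averaged over loci. F_IS is the Weir–Cockerham
single-sample f, 1 − Σc/Σ(b+c) over loci and alleles; the test suite proves
it equal to the indicator-variable ANOVA form to 1e−9.

The HWE exact test shuffles allele copies into genotypes conditional on
allele counts and uses the probability-ordering criterion (tables no more
probable than the observed one count toward p); the LD test permutes one
locus's genotypes and scores the G statistic on the genotype × genotype
table. Both are Monte-Carlo tests with seedable generators.

Null alleles are estimated with the Dempster EM algorithm: apparent
homozygotes are mixtures of true homozygotes and visible×null
heterozygotes; observed missing genotypes count as null homozygotes by
default (the FreeNA convention, toggleable). The log-likelihood ascent is
recorded and asserted monotone. Individuals typed at fewer than 9 of 11
loci are dropped by `drop_poorly_typed`, mirroring the study's inclusion
rule.

## Differentiation

F_ST is Weir–Cockerham θ (per-allele variance components a, b, c summed
over loci and alleles; Σa/Σ(a+b+c)); R_ST is Slatkin's (S̄ − S_W)/S̄ from
allele-size variance with numerators and denominators summed over loci;
Φ_ST is the two-level AMOVA index on pairwise sequence-difference counts.
Negative estimates are retained (not truncated), matching common practice;
monomorphic comparisons are flagged NaN.

The hierarchical AMOVA computes three-level sums of squares from a squared
distance matrix with the standard unequal-size coefficients (n₁, n₂, n₃);
the test suite verifies the variance components against an independent
textbook nested random-effects ANOVA on scalar data to 1e−9. Permutation
schemes follow the classic implementation: Φ_ST permutes individuals among
all populations, Φ_SC individuals among populations within groups, Φ_CT
whole populations among groups. Microsatellite AMOVA uses allele-identity
distances by default (squared-size distances optional); loci missing in
either member of a pair are skipped.

SAMOVA maximizes F_CT by simulated annealing over partitions constrained to
a 3-nearest-neighbour great-circle adjacency graph of the populations
(the original tool's Voronoi construction is not described in the study;
k-NN adjacency is this package's documented substitute). Moves reassign one
population to a neighbouring group, keeping all k groups non-empty;
geometric cooling, best-of-restarts, and a population-among-group
permutation test for significance. Because the observed F_CT is itself a
maximum over partitions, the p-value shares the anticonservatism of the
original method. Default 100 annealing steps, k scanned over 2…5.

## Median-joining networks

The construction iterates: build the ε-relaxed minimum-spanning network
(a link qualifies when its Hamming distance is within ε of the bottleneck —
minimax-path — distance between its endpoints, so ε = 0 gives exactly the
MSN), propose quasi-medians (per-site majority consensus; three-state sites
branch into all resolutions, capped at 8 per triple and 200 medians total),
and keep medians that shorten the spanning length. The parsimony cleanup
removes median vectors not on any shortest observed-to-observed connection
and splices out degree-≤2 medians (safe because edge weights are Hamming
distances, so the triangle inequality preserves path lengths); surviving
medians are genuine branch points (degree ≥ 3). On homoplasy-free data the
result is a tree whose length equals the number of variable sites — the
Steiner optimum — which the test suite asserts.

## ABC model choice

Summary statistics per dataset (microsatellites only, matching the study's
choice): per population mean alleles/locus, mean unbiased He, mean
allele-size variance; per population pair Weir–Cockerham θ, (δμ)² (squared
difference of mean allele size, averaged over loci), and an allele-sharing
distance 1 − Σ min(p, q). Rejection keeps the ⌈τ·rows⌉ rows with smallest
Euclidean distance on SD-normalized statistics (τ = 1 % by default, ties
broken by row index). Posterior probabilities come from a multinomial
logistic regression on linear-discriminant projections of the retained
rows (axes = min(#scenarios − 1, #stats); projections standardized before
the ridge-regularized logit), evaluated at the projected observation;
confidence intervals are a nonparametric bootstrap (200 refits) over
retained rows, and a scenario is "selected" only when its 95 % CI does not
overlap the runner-up's. `confusion_matrix` calibrates the whole pipeline
with pseudo-observed datasets of known origin.

Desk-scale defaults are deliberate: 6 scenarios × 10³–10⁴ simulations
rather than the production 14 × 10⁶; all 14 scenarios and larger tables are
available by configuration. At the 6 × 10⁴ scale the acceptance suite shows
every generating scenario recovered above chance (mean posterior on the
true scenario > 1/6) and admixture-founded-west data selecting the correct
scenario; mirror-image scenario pairs (e.g. whether the pulse founds the FR
or the SP lineage) remain weakly identified at this scale, which is an
honest property of the statistics, not an implementation artefact.

## What the synthetic generator does and does not emulate

It reproduces the sampling layout, marker panel, mutation processes and the
candidate demographic histories. It does not emulate genotyping artefacts
(stutter, allelic dropout — null alleles are simulated only in the EM tests
where they are the object of study), missing-data patterns, sequencing
error, recombination, selection, or within-region spatial structure.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the tests under the stated models, not robustness to every
artefact of real field data.

## Problem sizes and numerical conventions

Test and default problem sizes (e.g. 999 permutations instead of 90 000,
2000 coalescent replicates, 6 × 10⁴ ABC tables) were chosen as the package's
desk-scale defaults; every count is a parameter. Empirical p-values always
use the +1 correction and never return 0. EM stops at |Δp| < 1e−8 or 10⁴
iterations; the annealing temperature schedule is T₀ = 0.1 with factor 0.95
per step. Seeds fan out from a single integer through `SeedSequence.spawn`,
so toggling one pipeline stage never perturbs another.
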
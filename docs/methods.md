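# Methods

This note documents the statistical models, algorithmic choices and
limitations behind `methylcompare`.  Notation: test 1 is the probe-based
array (beta-values β ∈ [0,1] with per-cell detection P-values, two Infinium
probe chemistries called "type 1" and "type 2"), test 2 is the
enrichment-based capture-sequencing assay (deduplicated mapped fragments).

## Dichotomization

Both platforms are reduced to binary presence/absence-of-methylation calls
per CpG locus and sample:

- **Array**: call = 1 iff β ≥ t, with t on the grid {0.2, 0.3, 0.4}.  The
  comparison is inclusive (β exactly at the threshold is methylated); the
  boundary convention is not forced by anything and is configurable.  Cells
  with detection P > 0.05 are unreliable measurements and become missing.
  A 0.1 threshold sits below the bulk of the unmethylated beta component
  and is excluded from the default grid, though the config accepts it.
- **Capture**: call = 1 iff at least one fragment's interval contains the
  CpG coordinate (half-open containment of the single base; an optional
  ±window widens the query).  Samples with fewer than 2 million total
  mapped fragments are flagged for exclusion — below that depth the
  ≥1-fragment rule is dominated by sampling noise.
- **M-values**: log2((β+ε)/(1−β+ε)), used for the quantitative spot-check
  of differential loci (Welch-type tests).  With ε = 0, betas are clamped
  to [1e−6, 1−1e−6] to avoid infinities; the transform is strictly
  increasing, so beta-threshold and M-threshold calls are equivalent.

## Latent-class model without a gold standard

Neither platform can adjudicate the other, so the true status D ∈ {0,1} of
each locus is latent.  For one population and two possibly dependent
binary tests the model has seven parameters: Se₁, Se₂, Sp₁, Sp₂,
prevalence π, and within-class covariances covp (methylated class) and
covn (unmethylated class).  Within the methylated class, the joint
probabilities of the four paired outcomes are

    P(+,+|D=1) = Se₁Se₂ + covp        P(+,−|D=1) = Se₁(1−Se₂) − covp
    P(−,+|D=1) = (1−Se₁)Se₂ − covp    P(−,−|D=1) = (1−Se₁)(1−Se₂) + covp

(analogously with Sp and covn for D = 0), which forces each covariance
into the feasibility range
max(−a₁a₂, −(1−a₁)(1−a₂)) ≤ cov ≤ min(a₁(1−a₂), (1−a₁)a₂); zero
(conditional independence) is always feasible.  The data per sample are
the 2×2 cross-tabulation of complete paired calls (pairwise-complete:
loci missing in either test are dropped and counted), with a multinomial
likelihood over the four marginal cell probabilities.

**Identifiability.**  The data carry three degrees of freedom against
seven parameters, so the posterior concentrates on a curved 4-dimensional
ridge and priors matter.  Two structural choices:

- The model is exactly invariant under relabeling the latent classes
  (Seᵢ ↔ 1−Spᵢ, π ↔ 1−π), which makes the posterior bimodal and multichain
  diagnostics meaningless.  The sampler therefore truncates the prior to
  the standard better-than-chance region Seᵢ + Spᵢ > 1 (switchable via
  `MCMCConfig.constrain_accuracy`).
- Only the cell probabilities are identified.  Point summaries of the raw
  parameters (posterior medians) are honest posterior quantities but are
  pulled toward the ridge interior by the flat prior; orderings between
  tests (e.g. which test has the higher specificity) are preserved and are
  what the cohort comparison reports.  `PosteriorSummary.implied_cell_probs`
  summarizes the identified functionals per draw.

**Priors.**  Beta(1,1) on the five probability parameters (overridable
per parameter via `prior_a`/`prior_b`), truncated as above, and uniform
over the dynamic feasibility bounds for each covariance.  The exact prior
used by the original WinBUGS-era implementations of this model family is
not recoverable; these defaults are the common weakly-informative choice
and are documented rather than asserted as anyone else's.

**Sampler.**  Random-walk Metropolis-within-Gibbs over the seven
parameters cannot traverse the curved ridge at any affordable length (the
likelihood pins three directions at width ~N^{−1/2}, making along-ridge
moves diffusive; R̂ stayed above 1.2 even at 4×100,000 iterations).  The
production sampler is therefore a data-augmented Gibbs scheme, the same
family of kernel a BUGS Gibbs engine derives for this model:

1. *Augmentation* — for each observed cell, the number of truly
   methylated loci is binomial with odds π·q_m(cell) : (1−π)·q_u(cell).
2. *Prevalence* — conjugate Beta update from the augmented total.
3. *Class simplices* — the four joint-outcome probabilities of each class
   get an independence-Metropolis update with a Dirichlet(1 + counts)
   proposal.  The multinomial likelihood cancels against the proposal
   exactly, leaving only the smooth prior factor in the acceptance ratio.
   The map (Se₁, Se₂, covp) ↔ methylated-class simplex has unit Jacobian
   (likewise specificities), so the stated priors transfer exactly: Beta
   densities on the accuracies plus −log(bound range) for the uniform
   covariance prior, plus the truncation indicator.

Chains start overdispersed from the prior; the first half of the
iterations is burn-in; draws are thinned on request.  Everything is
vectorized across chains and deterministic given the seed.  The default
profile is 5 chains × 200,000 iterations; desk-scale profiles (4 × 20,000
to 4 × 120,000) are used in tests and the acceptance script, with
problem sizes (tables of 10,000–50,000 loci) chosen so the ridge is
traversed within the profile — mixing time grows with the table size, and
at 10,000 loci per sample 4 × 120,000 iterations converges ~80–90% of
samples, comparable to the original analyses' experience.

**Diagnostics.**  Classic (non-split) Gelman–Rubin
R̂ = sqrt(((n−1)/n·W + B/n)/W) per parameter on post-burn-in draws, with
the split variant available; convergence is declared iff every R̂ < 1.1.
Both variants agree with the `arviz` reference implementation to < 1e−6.
The sampler itself is validated by simulation-based calibration: truths
drawn from the prior, tables simulated, and the truth's rank among thinned
posterior draws is uniform for all seven parameters (chi-square GOF).
Ranks are only uniform when the compared draws are nearly independent, so
the calibration uses thinning ~120 at 2 × 12,000 iterations.

**Degenerate inputs.**  An all-zero table is rejected.  Perfect-agreement
tables (two identical call vectors) leave π unidentified — the posterior
spreads over the agreement boundary of the ridge and the convergence flag
correctly reports failure, while the implied cell probabilities still
match the observed frequencies.

## Region calling and genomic context

A **methylated region** is a maximal run of bases with fragment coverage
≥ 1; a single uncovered base splits regions, so fragments abutting exactly
([a,b) then [b,c)) merge.  Implemented as interval-union with
merge-on-touch; verified exhaustively against a per-base coverage scan.
A region's representative position is the midpoint of its covered bases,
floor((start+end−1)/2).

**CpG-island context** partitions the genome exactly into island (merged
island annotation), shore (within 2 kb of an island), shelf (the next
2 kb) and open sea, with precedence island > shore > shelf resolving
collisions between nearby islands.  Overlapping islands in the source
annotation are merged before shore computation.

**Functional context** partitions the genome into promoter (strand-aware
[TSS−1.5 kb, TSS+0.5 kb): on the − strand the window is mirrored, genomic
[TSS−499, TSS+1501) for TSS = end−1), exon, intron (remaining
transcript-body bases), pseudogene and intergenic, with precedence
promoter > exon > intron > pseudogene.  Promoter/exon/intron layers are
built from non-pseudogene transcripts only; pseudogene bodies keep
whatever is not already claimed (truncated where they overlap real-gene
features).  If pseudogene transcripts also seeded promoters, the
pseudogene class would lose its own flanks to the promoter layer, which
would contradict the truncation rule.

Both partitions satisfy an exact conservation law — label lengths sum to
the genome length with empty pairwise intersections — checked as an
integer identity in the tests.  Regions spanning a partition boundary are
classified by their center alone.

The **probe/region ratio** (count of probe loci with non-zero coverage
over count of methylated regions) summarizes how much of the capture
platform's genome-wide signal the array interrogates; using a ratio
implicitly adjusts for sequencing depth.  Count comparisons between
platforms paired by sample use the Wilcoxon signed-rank test (the paired
"signed rank" design; Kruskal–Wallis is available behind a flag), and
context proportions are compared by chi-square against a reference
distribution.

## Differential methylation

Loci constant across all samples (all-0 or all-1 among non-missing calls)
carry no contrast and are removed.  Each retained locus gets a two-sided
Fisher exact P from its group × call table (point-probability method: sum
of hypergeometric probabilities ≤ the observed table's, with a 1+1e−7
relative guard against float noise; validated against an independent
implementation for every table with N ≤ 40).

Because Fisher P-values are discrete and their null distribution varies
with each locus's margins, standard FDR machinery is inappropriate; the
permutation FDR used instead is: permute group labels independently per
locus (preserving each locus's methylation frequency exactly), compute
one null P per locus, and for the i-th smallest observed P set
FDR_i = #{null ≤ P_(i)}/i.  The significance cut is the largest i with
FDR_i ≤ q, with all loci tied at that P flagged.  This estimator assumes
all loci are null (conservative) and ignores inter-locus dependence.

*Stability of the minimum*: with a single null per locus, whether the
globally smallest P lands on the observed or the null side is roughly a
coin flip, so the method sporadically flags 1–3 loci under a global null.
`permutation_null(..., n_rounds=R)` pools R independent permutation
rounds (the FDR renormalizes by the null/observed cardinality ratio),
bounding the spurious-minimum probability by 1/(R+1); R = 20 keeps it
under 5%.  The literal single-round procedure remains the default.

The **binomial detection criterion** asks how many of n samples must show
capture signal at a CpG before its detection rate significantly exceeds a
background (non-specific capture) rate p₀: the smallest k with
P(Binomial(n, p₀) ≥ k) < α, strict inequality.  For n = 70, p₀ = 0.10,
α = 0.05 the answer is 12.  Candidate-DMR summaries count intervals with
at least one qualifying CpG ("any") or at least ceil(n/2) of them
("half"), and the fraction of intervals containing ≥ 1 probe position.

## Ordination and the global test

Between-sample distances are d = √(1−s) with Jaccard similarity
s = a/(a+b+c) over pairwise-complete loci (a = both methylated; b, c =
discordant).  The square-root form is Euclidean-embeddable, so classical
principal coordinates (Gower double-centering of −½d², eigendecomposition,
coordinates = eigenvectors × √eigenvalue) reconstruct the distances
exactly and produce no negative eigenvalues; the plain 1−s form is
available, with negative eigenvalues dropped and counted.  The group
contrast is tested on all positive axes by the between-group inertia ratio
(group-size-weighted centroids) under uniform label permutations, with the
add-one P-value (1+#{perm ≥ obs})/(1+n_perm); 1,000 permutations by
default.  Type-I error is calibrated: under exchangeable labels the test
rejects at the nominal rate.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (config, seed).  The latent truth
D[l,s] ~ Bernoulli(π + δ_l·group_s) uses π = 0.515 by default — the
mid-threshold, type-1-chemistry prevalence regime — with 5 controls and
the remainder cases, and differential loci carrying δ = 0.45 at 5% of
loci where a contrast is wanted.  From D:

- *Paired calls* follow the latent-class model exactly (joint outcome per
  cell drawn from the class-conditional 2×2), at the default operating
  point Se₁ = 0.743, Sp₁ = 0.868 (array), Se₂ = 0.525, Sp₂ = 0.938
  (capture), covp = 0.02, covn = 0.005 — a mid-threshold type-1 regime
  with mild positive dependence.  Empirical conditional rates converge to
  these values (checked at 10⁵ loci).
- *Beta-values* come from Beta mixtures: methylated Beta(1.2, 1.0),
  unmethylated Beta(1.1, 6.0), chosen so that thresholding at 0.3
  reproduces the operating point (implied Se ≈ 0.76, Sp ≈ 0.86).  Type-2
  probes shrink draws toward 0.5 by a factor 0.3, mimicking that
  chemistry's compressed distribution.  Detection P-values exceed 0.05
  for ~0.1% of cells.
- *Fragments* are Poisson around each CpG with rate
  depth·density/(density+24) when methylated and depth·ε, ε = 0.02, when
  not; fragments are ~200 ± 20 bp, jittered ±80 bp.  With the default
  depth 3.5 this gives capture specificity exp(−0.07) ≈ 0.93 and
  sensitivity ≈ 0.55 at the type-1 median CpG density of 7 (≈ 0.39 at the
  type-2 median of 4), reproducing the assay-type-dependent capture bias.
  The half-saturation constant 24 is set by this operating point.  A
  single combined bias weight stands in for separate capture- and
  sequencing-step biases.
- *Background sites* let the capture assay see methylation the array
  never assays (its genome-wide character).  On a real genome probes are
  kilobases apart; the 2×1 Mb fixture genome is ~50× denser in probes,
  so background sites keep a ≥500 bp clearance from probes to prevent
  neighbor fragments from contaminating probe coverage — emulating real
  sparsity rather than measuring it.
- *Genome fixture*: two 1 Mb sequences; islands spaced > 8 kb so default
  shores/shelves never collide; genes on both strands with exons and a
  ~10% pseudogene fraction; 200 candidate-DMR intervals.

Not emulated: sequence content (no reads, no bisulfite chemistry, no GC%
separate from CpG density), array probe cross-reactivity and SNP
artifacts, spatial correlation of methylation along the genome, and
genome-scale sparsity ratios.  Consequently, passing tests demonstrate
the correctness of the machinery under the stated observation model, not
platform performance on real tissue; and statistics whose magnitude
depends on genome-scale geometry (the probe/region ratio in particular)
take fixture-specific values — on the compact fixture the ratio lands
near 0.5, whereas genome-scale data put it far lower.

## Problem sizes and numerical conventions

All coordinates are 0-based half-open; BED is native, TSV matrices carry
`NA` for missing, matrices align by header names rather than position.
The test suite and acceptance script run at desk scale: latent-class
recovery at 50,000 loci (4 × 20,000 iterations), cohorts of 10 samples ×
10,000–20,000 loci, simulation-based calibration with 200 replicates of
300-locus tables, differential cohorts of 10,000 loci × 68 samples, and
ordination cohorts of 20 samples.  Tolerances follow from the statistics:
Monte-Carlo assertions use 3-standard-error bands, identified-functional
recovery uses 0.01 per cell (≈ 3·√(p(1−p)/N) + margin at N = 5·10⁴), and
exact identities (partition conservation, per-base region equality,
closed-form kappa and R̂) are asserted exactly or at float precision.

## Known limitations

- Raw-parameter posterior summaries inherit prior sensitivity from the
  non-identified ridge; cross-test orderings and cell probabilities are
  the robust outputs.  Informative priors (via `prior_a`/`prior_b`)
  shrink the ridge if external calibration exists.
- R̂ convergence rates depend on table size; very large tables need the
  full 200,000-iteration profile and may still flag a minority of
  samples, which the cohort summaries then exclude.
- The permutation FDR ignores dependence between loci; under global
  methylation shifts it is anti-conservative in the same way as in any
  pooled-null design.
- The capture observation model ties fragment rates to annotated CpG
  sites only; coverage between sites is zero by construction, so region
  counts are lower bounds relative to a diffuse-background model.
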
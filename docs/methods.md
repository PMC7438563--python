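# Methods

`gocsim` simulates a closed aquaculture-style breeding nucleus under genomic
optimal-contribution (GOC) selection and measures how the choice of
relationship matrix used for diversity management drives allele frequencies.
This note records the model, its parameters, the numerical choices, and the
known limits of what the simulations show.

## Base population

Haplotypes are generated at mutation–drift–linkage equilibrium for a diploid
effective size `ne` (default 100) with infinite-sites mutation at `mu`
(default 1e-8 per bp per generation) on `n_chromosomes` (default 10)
chromosomes of 1 Morgan each. Two interchangeable backends exist:

* **coalescent** (default): msprime with a binary infinite-sites mutation
  model. The stationary coalescent is the limit the forward process reaches
  after ~4 Ne generations, and only the final haplotype pool is consumed
  downstream.
* **forward**: an explicit diploid Wright–Fisher simulation with Poisson
  recombination, usable at small parameter values and kept as a fidelity
  cross-check (heterozygosity ≈ 4 Ne mu, declining site-frequency spectrum).

The default physical scale is 140 Mb per chromosome. With a 200-haplotype
pool sample this yields on the order of 33,000 segregating sites, and the
uniform genetic map makes length thresholds convertible between cM and Mb
(1 Morgan ↔ 140 Mb).

The 2000 generation-0 individuals are produced by one round of random mating
among the pool individuals (default pool: 200 haplotypes = an Ne = 100
population), so every founder gamete is a fresh recombinant of the pool.
This mirrors a nucleus founded from a small closed population: founder
chromosomes share long identical segments, roughly 20 gametes carry any
given pool segment, and the rarest panel alleles have base frequencies
around 0.5 %. We also explored sampling the pool at the nucleus size (4000
haplotypes): it floods the panels with ultra-rare alleles (p0 down to
1/4000) whose standardized contributions dominate every drift-based
statistic, and it is inconsistent with a segregating-site count rooted in a
small WGS sample, so the small-pool expansion is the default.

## Panels and trait

Four disjoint panels of 7000 loci are drawn uniformly (without replacement)
from the sites still segregating among the founders: M (markers for GEBVs
and, usually, for management), Q (additive QTL), N (untouched neutral
monitor), D (alternative management panel). At each locus a reference
allele is chosen at random; its generation-0 frequency `p0` is recorded from
the 2000 founders and reused, frozen, in every later generation for
standardizations and inbreeding measures.

QTL receive i.i.d. standard-normal allelic effects rescaled once so founder
true-breeding-value (TBV) variance is `sigma_g2` = 1; TBVs are centred to
founder mean 0, so reported gains are in base genetic SD units. Phenotypes
add N(0, `sigma_e2` = 1.5) noise, giving h² = 0.4. Only test sibs are
phenotyped (sib-testing: candidates carry genomic data only).

## Breeding scheme

2000 offspring per generation. Generation 1 is produced by 100 random sires
× 100 random dams (monogamous pairs, 20 offspring each) purely to create a
sib-family structure; these counts are configurable and were chosen to match
the Ne = 100 scale of the scheme. Every full-sib family is split as evenly
as possible into candidates and test sibs (odd member: seeded coin flip).
Candidate sexes are assigned 50/50.

From generation 1 onward each round runs:

1. SNP-BLUP on the current generation's 1000 test-sib records (training is
   per-generation; phenotypes do not accumulate across generations), with
   X standardized by the frozen p0 and ridge parameter
   λ = N_SNP σe²/σg². When records < markers the equivalent n-dimensional
   (GBLUP-form) system is solved; the two routes agree to machine precision
   and that equivalence is a standing test. Candidate GEBVs are ĝ = X_cand b̂.
   A control mode replaces ĝ with fresh i.i.d. N(0,1) draws.
2. A relationship matrix over the candidates (see below) repaired to
   positive definiteness.
3. Optimal contributions: maximize c'ĝ subject to c'Gc/2 = K_t, per-sex sums
   of ½ and c ≥ 0, with K_t = K_{t−1} + ΔF(1 − K_{t−1}), ΔF = 0.005, and
   K_0 = mean(G)/2 over the generation-1 candidates (diagonal included).
4. 2000 offspring, each drawing its sire (dam) independently from the males
   (females) with probability 2c_j — "random mating guided by the optimum
   contributions".

### Contribution solver

The closed-form Lagrangian stationary point on the active candidate set is
re-solved after eliminating all negative-contribution candidates, per the
classical active-set scheme. Two safeguards are layered on top: a KKT check
that re-admits eliminated candidates whose reduced gradient is positive
(the one-pass heuristic is occasionally suboptimal), and a retry with
single-candidate elimination plus an SLSQP polish for the rare paths where
aggressive elimination strands the iteration. The constraint acts as a cap:
if K exceeds the coancestry of the best-male/best-female solution that
unconstrained optimum is returned, so relaxing K never reduces the attained
objective. If K is below the minimum coancestry achievable on the
sex-constrained simplex, the coancestry-minimizing solution is returned and
flagged infeasible so long runs stay alive.

### Relationship matrices

* `A` — pedigree numerator matrix, founders unrelated/non-inbred; inside the
  scheme it is propagated generation-by-generation (algebraically identical
  to the tabular method for discrete generations).
* `G_VR2` = XX'/N and `G_VR1` = ZZ'/Σ 2p0(1−p0) (VanRaden methods 2 and 1)
  on base-frequency-standardized / centred genotypes.
* `G_0.5` — VanRaden form with all reference frequencies at 0.5; entries
  are proportional to expected progeny homozygosity.
* `G_i(p)` — cumulative-intensity matrix via the angular transform
  ι = 2[arcsin √(m/2) − arcsin √p0], the integral of di/dp = [p(1−p)]^−1/2;
  this construction is a declared stand-in with the stated intent (the
  original's exact recipe is not public) and agrees with the G_VR2
  standardization to first order around p0.
* `G_ROH` — mean genome fraction in shared haplotype segments over the four
  haplotype pairings (diagonal 1 + F_ROH). Segments are maximal runs of
  allelic agreement owning the midpoint intervals between neighbouring loci,
  with a ≥ 7 Mb threshold, no heterozygote allowance and no minimum marker
  count; these detector conventions are configurable because published ROH
  definitions vary.
* `G_LA` — IBD relative to generation 0. The default evaluator reads the
  simulator's founder-descent mosaics and is exact at the evaluation loci
  (a thinned grid, every 10th Panel-M locus, for tractability); a
  marker-HMM evaluator (two-state inhomogeneous forward–backward per gamete,
  Haldane transitions, phased parents) is provided for small pedigrees and
  converges to the exact evaluator as marker density grows.

Cross-product matrices get α = 0.01 added to the diagonal (they are PSD with
a zero eigenvalue from centring); `A`/`G_LA` need none; `G_ROH` can be
indefinite and uses the escalation schedule (start 0.05; on Cholesky failure
double while α < 1, else add 1).

## Inbreeding measures

Per panel, against frozen p0: `F_hom` = 1 − mean(H_t/H_0) (can be negative),
`F_drift` = mean(δp²/(p0(1−p0))) (non-negative, unbounded). Their difference
equals, exactly and per configuration, twice the mean standardized
cross-product between δp and (p0 − ½) — the algebraic identity at the heart
of the analysis, tested to 1e-12. Loci fixed by generation t are retained
(denominators use H_0 > 0). Rates ΔF come from OLS of log(1 − F_t) on t
with an intercept; both −slope and 1 − exp(slope) are reported
(indistinguishable at realistic rates). When an extreme scheme drives
F_drift ≥ 1 the regression uses the pre-saturation portion of the series.

Frequencies p_t are measured on all 2000 individuals of generation t; gain
is the mean TBV of generation-t candidates (founder mean = 0); genetic
variance is the TBV variance of all individuals.

## Experiments

`run_experiment` runs each scheme on shared replicates: within a replicate
the pool, panels, QTL effects and the generation-1 random-selection
generation are identical across schemes, removing simulation error from
between-scheme contrasts; randomness downstream of selection is
scheme-specific. Summaries are across-replicate means with SE = SD/√n.
`paired_comparison` interpolates a comparison scheme's gain against overall
inbreeding (mean of F_hom and F_drift on Panel N) at the reference scheme's
final inbreeding and counts strict per-replicate wins.

Problem sizes used by the shipped entry points: the acceptance script runs
the five headline schemes at the full model constants (2000 offspring,
7000-locus panels, 20 generations) over 2 shared replicates; the test
suite's reduced study uses 3000-locus panels and 3 replicates. Across-
replicate SEs quantify the remaining sampling noise in both cases.

## What the generator does and does not emulate

The generator reproduces the study conditions: equilibrium WGS-like base
genomes with a rare-allele-heavy MAF spectrum, disjoint functional panels,
an additive polygenic trait, and sib-testing with genomic-only candidate
selection. It does not model genotyping error, non-additive gene action,
overlapping generations, unequal sex ratios, mortality, or real linkage
maps, so passing tests demonstrate internal consistency of the management
machinery under idealized genetics, not performance on real data.

## Known limitations

* The linkage-analysis matrix tracks descent identifiers rooted at
  generation 0. Because founder chromosomes are recombinants of a small
  pool, distinct founder gametes carry identical long segments; management
  of identifier-IBD therefore cannot see (and cannot restrain) selection
  that concentrates segment *states* across different founder lineages.
  A haplotype-similarity-based IBD matrix would; the original study used a
  haplotype-based approximation whose exact recipe is not public. As a
  result, under directional selection our `G_LA` scheme shows neutral-panel
  drift above its coancestry target, where a state-aware evaluator holds it
  at target — the random-GEBV control (`G_LA(~,M)`) does hold both rates at
  target, isolating the gap to selection-driven state concentration.
* Realized selection response is sensitive to the within-family accuracy of
  SNP-BLUP, which in turn depends on base-population LD structure that the
  source material does not pin down (pool size, expansion design). Under the
  defaults the realized GEBV accuracy is ≈ 0.6–0.66 and per-round gains and
  selection-driven drift at unmanaged loci sit correspondingly at the high
  end; a sensitivity sweep (degrading accuracy) moves every scheme's rates
  and gains smoothly toward lower values, without changing any sign or
  ordering conclusion.
* `G_i(p)` and `G_ROH` follow declared stand-in constructions; their
  magnitudes are fidelity-limited even though their signs and orderings are
  robust.
* The per-pair `G_ROH` matrix is O(n² · loci) and is the slowest matrix at
  full scale; it is exact but intended for moderate candidate counts.
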
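# Methods

`gocsim` simulates closed breeding schemes in which genomic
optimum-contribution selection (GOCS) can use one genomic relationship
matrix to predict breeding values and a different one to control
coancestry.  This note documents the model, its parameters, the numerical
choices, and what the reduced-scale defaults do and do not show.

## Genome and founder model

The genome is a set of equally long chromosomes carrying an equidistant
grid of candidate bi-allelic loci; a fraction `qtl_fraction` (default 1/8,
i.e. a 1:7 QTL:marker ratio) of candidate loci belongs to the QTL class.
At full scale the genome is pig-like: 18 chromosomes x 167 cM (3006 cM,
30.06 Morgans), 10^4 candidate loci per cM, mutation rate 4e-6 per locus
per gamete.

The founder phase runs a discrete-generation Wright-Fisher population of
constant size (default 50; 25 males, 25 females) with:

- **Recombination.** Crossover count per meiosis ~ Poisson(genome length in
  Morgans), positions uniform on the concatenated genome, starting strand a
  fair coin per chromosome (Haldane model, no interference, no sex
  differences).
- **Mutation.** Per gamete, Binomial(#monomorphic loci, mu) new mutations,
  each converting a uniformly chosen monomorphic locus to carry the derived
  allele on that gamete.  Mutation targets only currently monomorphic loci
  (a per-locus infinite-sites approximation); recurrent and back mutation
  are ignored.  A locus's marker/QTL class is drawn the first time it
  mutates and memoised — distributionally identical to classifying the
  whole grid up front, without 3e7-element state.
- **Selection.** Each generation the lowest ceil(5% N) of animals by true
  breeding value (TBV) are culled and replaced in a single resampling pass
  (replacements are not re-culled); parents are then drawn with replacement
  from the survivors.
- **QTL effects.** The derived allele at a QTL has additive effect with
  exponential magnitude, positive with probability 0.1 (so selection mostly
  purges deleterious derived alleles).  The ancestral allele's effect is 0.
  TBV_i = sum_j x_ij g_j over trait QTL, x_ij the derived-allele dosage.

Loci fixed for the derived allele are pruned from every haplotype each
generation; a fixed QTL adds the same constant to every TBV, and only TBV
differences enter any downstream computation.  After the final generation,
effects are rescaled by a single scalar so that the *population* variance
(divide by n) of TBV over the founder cohort equals 1.  Architectures with
fewer QTL (e.g. 1000 or 500 at full scale) are drawn by uniform subsampling
of segregating QTL and re-standardised; removed QTL cease to exist for the
trait and are excluded from every relationship matrix.

Haplotypes are stored sparsely (sorted arrays of derived-allele locus ids);
a dense dosage export exists for segregating loci, and the test suite
verifies sparse and dense paths give identical genotype and G matrices.

## Base population and IBD tracers

Each scheme replicate samples a base population (default 10 males + 100
females) from the founder chromosome pools: per animal and chromosome, two
copies drawn without replacement, pool restored before the next animal, so
base animals can share founder chromosomes.  The founder population is
simulated once and shared across replicates; the base sampling is what
differs between replicates.

Base animals are treated as unrelated and non-inbred.  IBD tracer loci
(4/cM at full scale, placed at midpoints of a uniform grid) receive 2n
distinct integer labels across the 2n base haplotypes; they recombine
jointly with all other loci in the same meiosis and never enter any G
matrix or GEBV.  True inbreeding of an animal is the fraction of tracer
loci at which its two labels coincide; the classical sire-daughter (1/4)
and half-sib (1/8) pedigree expectations are recovered by Monte-Carlo.

## Relationship matrices and G-BLUP

G = W D^-1 W' / L with W dosages centred by twice the base-population
allele frequency and D_ii = 2 p_i (1 - p_i) — the frequency-scaled form of
the genomic relationship matrix.  Base frequencies are computed once from
the base animals and frozen; loci monomorphic in the base are excluded
(D^-1 undefined), loci that become monomorphic later are retained.
Centring and scaling are invariant to which allele is called minor, so
derived-allele frequencies are used throughout.  Matrices come in three
sources: markers (G_M), trait QTL (G_Q), both (G_A); they grow
incrementally as generations are genotyped and the same matrix serves
prediction and/or coancestry control restricted to the relevant animals.

G-BLUP: y = 1 mu + Z g + e with Var(g) = G sigma_g^2, Var(e) = I
sigma_e^2.  Variance components are fixed at the simulation's true values
(sigma_g^2 = 1, sigma_e^2 = 4; h^2 = 0.2) — the schemes differ by matrix
choice, not by estimation noise — with a configuration hook for other
values.  The solver works in observed-data form, V = sigma_g^2 G_OO +
sigma_e^2 I (Cholesky), mu by GLS, gebv = sigma_g^2 G[:,O] V^-1 (y - mu):
V is positive definite even when G is rank-deficient (G_Q with few QTL),
so no ridge is needed on the main path.  An independent augmented
least-squares oracle (factor G, penalised regression) checks the solver to
1e-8 on full- and deficient-rank instances.

## Optimum-contribution selection

Contributions c maximise U(c) = c'g_hat - w c'Gc subject to the mating
structure: per-sex contribution sums of 1/2, integer sire mating counts
m_i with c_i = m_i / (2T), exactly T dams at one mating each (c = 1/(2T)).
The penalty weight w >= 0 prices the selected group's mean relationship;
published penalty grids quoted as negative values map to w = |omega|.

- **Continuous relaxation**: active-set iteration on the KKT system of the
  equality-constrained quadratic program, dropping negative contributions
  and re-freeing bound candidates whose multiplier indicates improvement;
  a ridge of 1e-8 x mean(diag G) is applied only if the KKT system is
  singular.  Verified against a generic SLSQP solver to 1e-6.
- **Integer search**: an elitist evolutionary algorithm over (mating
  vector, dam subset) — tournament selection, uniform crossover with
  repair to sum(m) = T, move-one-mating and swap-one-dam mutations —
  warm-started from the rounded continuous solution and a
  truncation-selection plan, so the returned objective never falls below
  either benchmark; exact on enumeration-sized instances and deterministic
  given the seed.  Default budget 6000 evaluations (4000 at reduced
  scale).
- **Mating**: sire slots (repeated by mating count) are paired to the
  selected dams by a uniform random permutation; each pair produces a
  fixed number of offspring.

`calibrate_omega` bisects log(w) against a caller-supplied scheme runner
until the mean realised rate of true inbreeding matches a target.

## Scheme structure

Generation 0 is the base (genotyped, never phenotyped).  Generation 1:
every base dam is mated once to a uniformly drawn base sire.  Generations
2-5: truncation selection on GEBV (full scale: top 10 sires and 100 dams,
10 dams per sire, 5 offspring per mating), mimicking a population under
selection; the scenario's prediction matrix drives these generations too
(configurable).  Generations 6-11: OCS over the previous generation's
candidates (full scale: 25 matings x 20 offspring).  Sexes are exactly
balanced in generations 1-5 and Bernoulli(1/2) afterwards — the two phases
of the scheme deliberately differ in their sex-assignment rule.  Phenotypes
P = TBV + N(0, sigma_e^2) are simulated at birth for every non-base animal
and records accumulate; every genotyped animal stays in the G matrices and
receives a GEBV.  No new mutations arise during the scheme: the locus set
is frozen at the base, where the G matrices' base frequencies are anchored.

Truncation ties break by (GEBV descending, id ascending).  A "random"
selection mode replaces both phases with equally contributing random
parents; with 25 + 25 parents it reproduces the classical rate of
inbreeding 1/(8 Nm) + 1/(8 Nf) = 0.01 and serves as an end-to-end check of
the transmission machinery.

## Metrics

Rate of gain: OLS slope of mean TBV of animals born in generation t on t
over the OCS span (default 6-11).  Rates of inbreeding (tracer-based or
pedigree Wright coefficients via the tabular method): 1 - exp(beta) with
beta the OLS slope of ln(1 - F_t) on t — exact on geometric series.
Accuracies: Pearson correlation of GEBV with TBV among final-generation
candidates, by sex.  Replicate aggregation reports means with the standard
error of the replicate mean.

## Reduced-scale defaults and what they show

One full-scale replicate (3e7 candidate loci, 1000 founder generations) is
not desk-sized.  The reduced preset keeps every structural ratio and
shrinks sizes: 2 chromosomes x 100 cM, 100 candidate loci/cM, mu = 4e-5
(raised so mutation-drift equilibrium carries ~700 segregating loci), 200
founder generations, 1 IBD tracer/cM, base 10 males + 50 females, 150
offspring/generation (truncation 10 x 5 x 3), OCS 15 matings x 10
offspring.  One replicate runs in a few seconds on one core.

The "moderate QTL" architecture at reduced scale uses 32 trait QTL
(segregating QTL number ~60-100 here, so the full-scale counts cannot be
taken literally): few relative to ~650 markers, which is the regime where
QTL-based prediction should outperform marker-based prediction, while keeping
the TBV distribution smooth.

Matched-inbreeding comparisons calibrate the penalty per scenario, because
realised dF at equal penalty depends on the prediction matrix.  At reduced
scale the per-replicate dF is as noisy as the 0.01 target itself, so
`headline_comparison` fits the dose-response by OLS of realised dF on
log(w) pooled over a small penalty grid (common random numbers across
penalties) and inverts it at the target; the bisection calibrator remains
available as `calibrate_omega` for less noisy settings.  Paired replicates
share the base population and scheme random streams across scenarios.

What reduced-scale success shows: the qualitative interaction — with few
QTL, predicting with G_Q while controlling coancestry with G_M yields more
gain at the same true inbreeding than M_M, driven partly by higher GEBV
accuracy.  What it does not show: full-scale magnitudes (gain rates,
accuracies and the LD structure of a 54k-marker panel are size-dependent),
LD decay matched to real livestock populations, or behaviour of the
very-many-QTL architecture, where the full-scale study found no scenario
differences.

## Known limitations

- Discrete generations only; no overlapping generations, fertility culling
  or genotyping-cost modelling.
- No recombination interference, sex chromosomes or non-equidistant maps.
- Variance components are assumed known; no REML/Gibbs estimation.
- Dam selection is part of the OCS search space; the original scheme
  definition fixes 25 dams at one mating each but does not say how they
  were chosen, so the optimiser chooses them.
- The evolutionary algorithm's parameters (population 32, tournament 2,
  mutation rates 0.8) are package choices; published descriptions of such
  optimisers leave them unspecified.
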
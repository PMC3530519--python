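# Methods

This note records the models behind `msatdemog`, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are unordered diploid allele pairs per individual × locus.
Genepop allele codes are converted to integer **repeat units** at load
time through a per-locus affine map (`size = (code − offset) /
motif_length`); all downstream mathematics lives on that lattice, which
is where the stepwise mutation model and the M-ratio are defined.  A
half-missing diploid call is promoted to fully missing so allele
tallies stay unbiased.  Deme labels and collection years travel in a
sidecar TSV because the Genepop format cannot carry them.  The QC rule
retains individuals typed at a configurable minimum number of loci
(default 7 of 10, the usual threshold for mixed museum/noninvasive
data).

## Summary statistics

* H_E is Nei's unbiased estimator `(2n/(2n−1))(1 − Σp²)`.
* F_IS and F_ST are Weir–Cockerham variance-components estimators
  (small f and θ); multi-locus and multi-allele combination is
  ratio-of-sums, the stable convention for rare alleles.  Negative
  estimates are reported as computed.
* R_ST applies the same one-way weighting to allele-size variance
  components, so pairwise R_ST and F_ST are directly comparable.
* Allelic richness is exact rarefaction
  `Σ_i [1 − C(N−N_i, g)/C(N, g)]`, by default at g = 8 gene copies
  (four individuals — the smallest fully typed group in the motivating
  design).
* Exact tests condition on margins.  Small tables are enumerated
  completely (Levene's distribution for one-locus genotype tables; the
  multivariate hypergeometric for contingency tables); larger tables
  are sampled iid from the same conditional law (random pairing of
  gene copies, or margin permutation).  iid sampling replaces the
  traditional Markov-chain walk because it needs no burn-in and is
  unbiased at any run length.  Across loci, genic differentiation
  combines with Fisher's method.
* The diversity comparison between groups is a paired t-test of
  arcsine-square-root transformed per-locus H_E, with locus masks so
  subsets of loci can be compared.  Multiple testing uses Holm's
  sequential Bonferroni (strict inequality, stop at first failure).

## Coalescent simulator

The generator is a time-rescaled Kingman coalescent: waiting times are
drawn on the cumulative-intensity scale Λ(t) = ∫dt/N(t), which is
closed-form (and closed-form invertible) for constant, exponential and
linear single-change trajectories, so no discretisation is involved.
Pairwise coalescence rate is 1/(2N(t)) (diploid convention,
θ = 4Nμ at equilibrium).  Mutations are Poisson on branches; a
mutation is ±1 repeat unit with probability `p_single`, otherwise a
signed geometric multistep.  Two multistep conventions coexist
because the two bottleneck tests use different ones:

* **variance convention** (heterozygosity-excess testing): magnitudes
  on {1, 2, ...} with `(1−p)/p² = variance`; variance 12 gives
  p = 1/4 exactly;
* **mean convention** (M-ratio critical values): "multistep" means
  *more than one step*, magnitudes on {2, 3, ...} with mean Δg, i.e.
  1 + Geometric(1/(Δg−1)); Δg = 3.5 gives p = 0.4.  This follows the
  definition of the parameters in the original M-ratio software
  (proportion of mutations *greater than one step*, and their average
  size); with multistep magnitudes on {1, 2, ...} the simulated
  equilibrium cutoffs at θ = 10 run ~0.04 low.

The root allele is 0 and reported sizes are offsets — every statistic
downstream is translation-invariant.  No allele-size boundary or step
cap is imposed.  Per-locus random streams are spawned from the master
seed, so any locus is reproducible in isolation.  Serial sampling
inserts lineages at their sampling times; island-model subdivision
runs a Gillespie structured coalescent over constant-size demes with
symmetric migration, optionally merging into the trajectory-governed
ancestral population at a split time.  A forward Wright–Fisher mode
exists solely for the mode-shift power experiment, where "breeding
individuals" semantics matter: an equilibrium coalescent sample founds
2N_b gene copies which are multinomially resampled each generation
(mutating at rate μ), and the final sample is drawn from the last
pool's frequencies.

The four-group study-shaped bundle (`study_scenario`) emulates:
two long-isolated populations each sampled twice ~19 generations
apart (95 years at 5-year generations) with sizes 5/148 and 16/127; a
decline from ancestral N_e ≈ 1800 to current ≈ 150 at ~300
generations; and a contemporary population subdivided into three demes
of 50 with migration 0.05 per lineage per generation, which a
calibration test shows realises mean pairwise F_ST ≈ 0.07 (inside the
moderate 0.05–0.13 band).  What it does **not** emulate: genotyping
error and allelic dropout, isolation by distance within demes,
unequal locus mutation rates, or null alleles — so green tests say the
*methods* behave correctly on idealised data, not that real museum
data are this clean.

## Bottleneck detectors

*Heterozygosity excess.*  For each polymorphic locus the equilibrium
H_E distribution conditional on the observed allele count k and sample
size is simulated by rejection in two phases: a stochastic-
approximation phase walks a working θ toward values whose equilibrium
allele count matches k, then θ is frozen and only exact-k replicates
are collected (collecting while θ still adapts mixes conditioning
levels and biases the null mean low).  Default 5,000 conditioned
replicates per locus.
The across-locus test is a one-tailed Wilcoxon signed-rank on the raw
differences He_obs − mean(Heq), exact for ≤ 25 informative loci;
standardized differences are reported for inspection.

*Mode shift.*  Alleles from all polymorphic loci are pooled into ten
frequency classes of width 0.1; the spectrum is shifted when the
rare class [0, 0.1) holds strictly fewer alleles than some higher
class (ties conservatively count as not shifted).  Below 30
individuals the test refuses to run (high type-I error).

*M-ratio.*  Per locus M = k/s with s = (max − min) + 1 occupied-state
count, bounding M in (0, 1] (the verbal "range" definition would allow
M > 1 for adjacent alleles); the multi-locus value is the unweighted
mean over polymorphic loci.  M-critical is the 0.05 quantile of the
equilibrium multi-locus mean M from (default) 10,000 simulated
datasets at the given θ and sample size; μ = 5 × 10⁻⁴ is carried in
the config for documentation but enters only through θ.

Measured behaviour worth knowing (computed by the sensitivity runs in
the test suite): the mode-shift test's power
against a collapse to 20 breeders sampled 5 generations later is
~0.3–0.45, rising to a plateau of ~0.65 by 10–20 generations; the
cited ≥ 0.8 detectability holds only for more severe collapses
(≤ 10 breeders) under this mutation model.  The acceptance script
reports the honestly computed value.

## Size-change inference

The model: ancestral size N1 changed to current size N0 at T
generations before sampling, N(t) interpolating exponentially or
linearly; loci evolve by strict stepwise mutation with per-locus
θ_i = 2N_0μ_i.  Each locus carries a latent genealogy (labelled
topology, node times in generations, integer ancestral states).  The
branch transition probability for a net displacement d over a branch
with expected mutation count m is the Skellam form e^(−m) I_|d|(m),
evaluated in the log domain by a multiplicative series recurrence
(verified against scipy's `ive` and a brute-force Poisson
convolution).  The coalescent density uses the same closed-form
intensities as the simulator.

Sampling is Metropolis–Hastings with, per iteration and locus, one
node-time move (uniform between the bracketing nodes; multiplicative
for the root, with the exact Hastings factor), one narrow-exchange
topology move, and one ±{1,2} integer random walk on an internal
state; then log-scale Gaussian random walks on log10 N0, N1, T, each
θ_i, and the hierarchical hypermeans and (zero-reflected)
hyper-SDs.  Priors are hierarchical log10-normals: x ~ N(α, σ),
α ~ N(α₀, a), σ ~ N(σ₀, s) truncated at zero; setting a = s = 0 pins
them (non-hierarchical mode).  Default centres: sizes 10³, time 10³
generations, θ 10⁰, prior SD 1 with hyper spread 0.5/0.25 — wide
relative to everything the motivating system could plausibly be.  A
short pilot (the burn-in fraction) adapts the demographic step size
once, after which scales are frozen so the recorded stretch satisfies
detailed balance.  T is parameterized in generations; conversion to
years (T × generation interval + sample age, default 5 years and
0/95 years) is purely presentational.

Correctness evidence in the suite: exact 2-leaf posterior agreement,
prior recovery from zero-locus runs (KS per parameter), translation
invariance, a reciprocal-Hastings check on the root move, and —
most stringently — agreement of P(N0 < N1) with an independent
marginal-likelihood oracle (simulated coalescent trees + exact
Skellam pruning over a truncated allele lattice) on a parameter grid.

**Known limitation (important).**  The same oracle shows that on data
simulated under *constant* N, the single-change model's own marginal
likelihood prefers (N0 small, N1 large) configurations by a few nats
even at tiny data sizes; the sampler therefore reports decline-leaning
posteriors on stable data.  This spurious-decline tendency of
single-sample size-change inference under stepwise mutation is a
model property, consistent with published critiques of such methods,
and is why Bayes factors (posterior odds against *prior* odds, with
the published 0.33/3/10 category thresholds) rather than raw posterior
mass should be read as the strength of evidence, and why the
motivating study's cross-validation across independent detectors
matters.  A stable-population calibration ("90% HPD of r covers 1")
is accordingly not a property this model can guarantee at desk-scale
data and is not asserted.

Desk-scale defaults are deliberately small (tens of thousands of
iterations, thinning to a few hundred records, 3–5 chains): the
synthetic datasets here are far smaller than the study's real data, so
chains converge orders of magnitude faster; every run length is
configurable.  The scaled-down decline-recovery experiment uses 40
diploids × 10 loci at μ = 10⁻³ (inside the textbook microsatellite
range): at μ = 5 × 10⁻⁴ the desk-scale data hold only ~3 alleles per
locus and the posterior is prior-dominated, i.e. the experiment would
measure data weakness, not method correctness.

## Post-processing

Chains drop a burn-in fraction (default 10%) for diagnostics and pool
the trailing 50% for summaries.  Convergence uses the Brooks–Gelman
MPSRF ((n−1)/n + ((m+1)/m)λ₁ with λ₁ the top eigenvalue of W⁻¹B/n);
the acceptance gate is a warning at 1.1, not a failure, because the
"≈ 1" convention has no canonical cutoff.  HPD intervals are
shortest-window scans on sorted samples; modes are Gaussian-KDE
argmaxes on the log10 scale, back-transformed (posteriors are near
log-normal).  Note the KDE argmax of a flat-topped density wanders by
~±0.15σ even at 2 × 10⁵ samples — modes are descriptive, HPDs are the
inferential quantity.  The Bayes factor for decline is posterior
odds(r < 1) / prior odds(r < 1) with prior odds from iid draws of the
hierarchical prior; zero counts use add-one continuity and are
flagged as a bound.  The "fraction of the change-time posterior older
than a reference date" is the pooled fraction of T-samples (in years,
after calibration) exceeding the reference horizon.

## Degenerate inputs and tie-breaks

Monomorphic loci: excluded from M-ratio means and heterozygosity-
excess testing (logged); He = 0; HWE/LD tests report p = 1 flagged
untestable.  Empty groups and unknown labels raise immediately.
Mode-shift ties → not shifted.  Wilcoxon with all-zero differences →
p = 1.  Exact-test "as extreme" comparisons tolerate 1 + 10⁻⁹
relative rounding.  M-ratio replicates with no polymorphic locus
report M = 1 (no evidence of loss).

## Measured operating characteristics

Two calibration facts, measured by the acceptance suite and worth
knowing before interpreting results on real data:

* The heterozygosity-excess test is anticonservative: at a matched
  two-phase equilibrium its one-tailed rejection rate at nominal
  alpha = 0.05 is about 0.08-0.11.  The cause is structural: the
  equilibrium He distribution conditional on the allele count is
  left-skewed, so the per-locus event "observed He above the
  conditional mean" has probability ~0.58 rather than 0.5, and the
  Wilcoxon signed-rank applied to mean-centred differences (the
  published construction, kept here) assumes symmetry.  Treat
  p-values near the threshold accordingly.
* The mode-shift test's power against a collapse to 20 breeders
  sampled 5 generations later is ~0.3-0.45 under two-phase mutation
  (plateau ~0.65 by 10-20 generations); the often-cited >= 0.8
  detectability is reached only for more severe collapses.
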
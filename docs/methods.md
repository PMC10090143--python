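# Methods

## Model

The simulator is a Wright–Fisher-like discrete-generation model with dynamic
population size.  State is the number of host cells in each *genotype class*
`(a, b)` — `a` wild-type and `b` mutant (constitutively lytic) copies of a
phage-plasmid — plus a pool of free virions awaiting infection.

Each generation, in order:

1. **Re-infection.**  Virions produced in the previous generation are placed
   uniformly at random, with replacement, over all live cells.  Each placement
   adds one mutant plasmid copy to its target; multiple hits accumulate.
2. **Division and segregation.**  Every cell duplicates its plasmid copies
   (2a wild-type + 2b mutant) and divides; each daughter receives `a + b`
   copies drawn without replacement from the duplicated pool, so a daughter's
   wild-type count is hypergeometric with the second daughter taking the
   complement.  Copy number per cell is conserved by division and increased
   only by re-infection.
3. **Lysis.**  Daughters with zero wild-type copies have lost all repressor
   dosage and lyse.  L lysed cells contribute Poisson(R·L) virions to the
   pending pool (deterministically round(R·L) in the `fixed` debug mode).  R
   is the *re-infection efficiency*: the mean number of released virions per
   lysed cell that go on to successfully infect a live cell.  Burst size and
   adsorption kinetics are not modelled separately; only their product R
   matters for the population genetics.
4. **Bottleneck** (every `gens_per_cycle` generations).  Each class count is
   thinned binomially with probability 1/d; free virions transfer with the
   supernatant and are thinned identically.

A single loss-of-function mutation can be seeded at a configurable generation
(one copy chosen uniformly among all wild-type copies in the population), or
mutations can recur at rate `mu` per newly replicated wild-type copy.  The
number of cells of a class receiving `e` mutated new copies is drawn
Multinomial(k, Binomial(a, mu)) — exact at any `mu`.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `n0` | 10⁶ | cells at the start of each dilution cycle |
| `gens_per_cycle` | 6 | doublings per cycle (N_t = N₀·2ᵗ) |
| `d` | 64 | dilution factor at transfer (= 2⁶, so the census returns to n0 absent lysis) |
| `r` | 5.0 | successful re-infections per lysed cell |
| `initial_wt_copies` | 1 | plasmid copies per founder cell |
| `seed_generation` | 0 | generation of the single seeded mutation |
| `mu` | 0 | recurrent per-copy loss-of-function rate (off by default) |
| `copy_cap` | none | optional ceiling on copies per cell; infections at the cap are dropped |
| `rng_seed` | 0 | every run is bit-reproducible from this seed |

These defaults are the study conditions of the serial-passage experiments the
model describes; `r = 5` is the value recovered by the package's own
inference stage from trajectories simulated under these conditions.

## Aggregation and its validation

Cost scales with the number of distinct genotype classes, not cells: division
uses one multinomial draw per class over the cached hypergeometric kernel,
and lysis/bottleneck operate on class counts.  Two aggregation approximations
are made, both validated against the per-cell agent implementation
(`ppsim.agent`), which keeps one record per cell, places each virion on an
explicitly chosen cell, and samples the bottleneck without replacement:

- **Virion placement.**  For populations up to 150 000 cells, placement is an
  exact balls-in-bins draw.  Above that, each class draws its cells'
  hit-count multiplicities from the Poisson occupancy law with rate v/N;
  because the virion count itself is Poisson, the compound law equals exact
  uniform placement in distribution (Poisson thinning), at cost independent
  of N.
- **Bottleneck.**  Binomial thinning per class approximates sampling cells
  without replacement; at a census of 10⁶ the two are indistinguishable.  The
  agent oracle implements the exact version (e.g. 64 cells diluted 1/64 leave
  exactly one), bounding the approximation at small N.

The acceptance suite compares 500 replicate pairs of the two simulators at
N₀ = 1000 over 4 cycles; per-generation mean allele frequencies agree within
3 standard errors at every generation.

## Observables

Per generation the simulator records the census, lysed cells, pending
virions, the copy-weighted mutant allele frequency (mutant copies over all
copies — the quantity population sequencing estimates), the mutant-carrying
cell fraction and heterozygote fraction (cell-level measures reported
alongside, since read-based and cell-based frequencies differ whenever copy
number varies), mean copy number, and an optical-density proxy
n_cells/(n0·2^(generation within cycle)) that registers lysis as a shortfall
from pure doubling.  Live cells are the only density the model tracks; clump
formation and extracellular DNA, which drive optical-density collapse in real
cultures, are outside its scope.

`saturation_frequency` averages the allele frequency over the final dilution
cycle.  `rise_within_cycle` reports the frequency exactly one cycle after the
first timepoint at which it reaches a detection threshold (default 5%, a
typical variant-calling floor); detection can be evaluated every generation
or restricted to cycle-end timepoints, matching a design that sequences the
population only at each transfer.

## Transient saturation

Because cells lyse only when they carry zero wild-type copies, no wild-type
copy is ever destroyed and the wild-type copy total doubles exactly every
generation.  The mutant copy total doubles, loses the lysed daughters' copies
and gains R per lysed cell, so the allele frequency is stationary only while
lysing daughters carry on average R mutant copies.  Re-infection makes
per-lineage copy number non-decreasing, so this balance is crossed rather
than held: under the defaults the frequency peaks near 50% of plasmid copies
(carrier fraction ≈ 80% of cells) about 7 cycles after seeding and then
declines by roughly 3 percentage points per cycle, to ≈ 36% at the end of a
12-cycle run.  The plateau is therefore a transient — slow on the scale of an
experiment, but not a fixed point.  Capping copy number does not stabilise
it: with a tight cap the susceptible pool is consumed (capped wild-type
segregants cannot be re-infected) and the mutant burns out entirely.

## Inference of R

`fit_reinfection_efficiency` recovers R by grid search.  For each candidate,
an ensemble of simulations (seeded at generation 0) provides the mean allele
frequency per generation; the loss is the mean squared error against the
observed frequencies (mutant reads / depth) at the observed generations.
Because the timing of the spontaneous mutation in data is unknown, the
simulated curve may be shifted later by up to one dilution cycle and the
best-aligned error is used — implemented as a time shift of the
seed-at-generation-0 ensemble mean rather than re-simulating per candidate
seeding generation, which is ~6× cheaper and exploits the near
translation-invariance of the dynamics (exact up to bottleneck phase).  The
squared-error objective is this package's construction; it is dominated by
the saturation plateau, which is what separates the candidates.

## Synthetic sequencing

`sequencing_noise` emulates population sequencing at the end of each dilution
cycle: mutant read counts are Binomial(depth, frequency) at each sampled
generation, default depth 100× (typical bacterial resequencing).  It models
no read-level artifacts — no mapping bias, no indel-calling error, no
reference bias — so tests passing on these data demonstrate correctness of
the population process and the inference machinery, not robustness to real
sequencing pathologies.

## Problem sizes used in the test suite

Checks that do not require the full census run at reduced, fixed sizes chosen
once: oracle equivalence at N₀ = 1000 (500 replicate pairs, 4 cycles);
R-monotonicity at N₀ = 10⁵ (8 cycles, 20 replicates per R in {1, 2, 5, 8});
R-recovery with a N₀ = 10⁴, 8-cycle template (50 datasets at depth 500, grid
{1, 2, 3, 5, 8}, 6 replicates per candidate); drift martingale with 500
heterozygous cells over 12 generations (200 replicates); dosage-delay
comparison with mu = 10⁻⁶ at the full 10⁶ census but R = 0, since the time of
*first* lysis cannot depend on re-infection.  The headline saturation and
rise quantities always run the full baseline (10⁶ cells, 12 cycles,
20 replicates).

## Numerical choices

- Hypergeometric probabilities come from `scipy.stats.hypergeom` (log-space
  internally), renormalised to sum to exactly 1.0 in floating point so they
  can seed multinomial draws; exact rational enumeration is the test oracle.
- Homozygous parents short-circuit to their single certain outcome.
- Replicate k of an ensemble uses an independent stream derived from
  `(base_seed, k)` so any replicate is reproducible in isolation.
- The agent bottleneck size is n//d plus a Bernoulli remainder, keeping the
  expected post-transfer census at n/d for any n.
- Extinction (no live cells) truncates the trajectory and sets a flag;
  ensemble averages treat an extinct culture's mutant frequency as zero.

## Known limitations

- No resource dynamics or density regulation: a lysis-depleted population
  stays depleted (growth is exactly ×2 per generation regardless of density).
- Virions neither decay nor persist beyond one generation except through the
  transfer dilution.
- No clumping/eDNA biophysics; the optical-density proxy only reflects the
  live census.
- Superinfection exclusion, reversion mutations and host-range variation are
  not modelled.
- The recurrent-mutation mode (`mu > 0`) is provided for qualitative
  waiting-time phenomenology; `mu` is not calibrated to a measured rate.
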
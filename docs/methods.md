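# Methods

## The model

`altload` studies whether early-acting inbreeding depression can itself be an
adaptation. The setting is a predominantly outcrossing hermaphrodite in which
a fraction σ of ovules is incidentally self-fertilized (the *primary selfing
rate*), inbreeding depression acting after seed development is severe
(selfed-seed fitness `w_inbred`, 0 = lethal), and mothers can *compensate*
embryos lost early in development. A recessive allele *A* that lowers early
embryo survival (1 − hs in heterozygotes, 1 − s in homozygotes) then acts as
a conditional signal of inbreeding: a rare allele is almost only homozygous
in selfed embryos, so its early expression kills embryos that were largely
doomed anyway and lets the mother replace them with a likely-outbred sibling.
The package makes this argument computable at three levels.

### Reproductive compensation

Two compensation mechanisms are implemented:

* **Backup embryo** — each seed holds two independently formed half-sib
  embryos; the backup matures only if the primary dies early; if both die
  there is no seed. With per-embryo viability V for a given mother, the
  probability a seed of class (genotype, origin) matures is
  `d·v·(2 − V)`, where `d` is the per-embryo class distribution and `v` the
  class viability.
* **Charlesworth maternal fitness** — maternal seed output is
  `(1 − p_m)^(1 − C)`, with `p_m = 1 − V` the mother's expected embryo
  early-death probability and `C` the extent of compensation; the embryo
  reaching the seed stage is drawn from the distribution conditional on
  early survival. `C = 0` is no compensation, `C = 1` full compensation.

Seed-stage selection on inbreeding status (1 vs `w_inbred`) follows in both
models. Selfing is per-embryo i.i.d. (each embryo of a family is
independently selfed with probability σ) — this matters: replacement of a
dead selfed embryo by a possibly-outbred backup is the entire selective
benefit, and it disappears under whole-family selfing.

## Closed forms (`altload.analytic`)

Writing ψ_Aa = (s/2)(h + σ/2 + p_A(1 − σ)) for the replacement probability
in rare heterozygous-mother families, the invasion growth rate of *A* under
lethal inbreeding is

    λ = (1 − h s) · (1 + (s/4)(h + σ/2)),

the per-transmitted-copy family fitness λ·(1 − σ) relative to the
population mean 1 − σ. Solving λ = 1 for σ gives the critical selfing rate

    crit.self(h, s) = 2h(3 + hs)/(1 − hs),

with slope 6 in h at h = 0: a partially recessive self-sacrificial allele
spreads when σ exceeds about 6h. At h = 0, λ = 1 + sσ/8 > 1 always — a
fully recessive allele of this kind is never disfavoured when rare — and
the expected frequency change of a rare allele is Δp = p_A (λ − 1) =
p_A(1 − σ)sσ/(8 w̄) with w̄ = 1 − σ. (Note the /8: only half of a rare
carrier mother's seeds carry the allele, so the allele-frequency gain is
half the family-fitness excess sσ/4; the corresponding change in
*heterozygote* frequency is twice Δp.)

With sublethal inbreeding depression, a fully recessive allele invades when

    w_inbred < s(1 − σ)/(4 − sσ).

This bound is exact when s = 1 (or w_inbred = 0), because then no AA adult
exists at invasion. When s < 1 and w_inbred > 0, selfed AA seeds reach
adulthood at O(p) and amplify the allele's spread beyond what the
two-mother-type bookkeeping captures, so the bound is *sufficient but not
necessary*: the exact dominant eigenvalue (from the recursion) can exceed 1
on both sides of it. Tests check the exact flip at s = 1 and sufficiency
for s < 1.

The frequency dependence that stops the spread is Bayesian: the posterior
probability that an embryo is inbred given AA homozygosity,
(σp_A/2)/(σp_A/2 + p_A²(1 − σ)), falls as *A* becomes common and is
increasingly exposed allozygously, so *A* is favoured when rare and
disfavoured when common.

## Deterministic recursion (`altload.recursion`)

The state is the joint (genotype × inbred-status) frequency vector among
reproducing adults in an infinite population; the pollen pool is the adult
allele frequency (pollen production is genotype-independent; only
ovule-side selection is modelled). One generation composes mating,
early-viability selection with compensation, and inbreeding-stage
selection, then renormalizes. The adult inbred-status flag is bookkeeping
only (its fitness cost is already paid), but carrying it supports any
`w_inbred` in (0, 1).

Numerical choices:

* **Invasion growth rate** — power iteration at allele frequency ε = 1e-8
  from all-outbred Hardy–Weinberg proportions, rescaling the A-carrying
  classes back to ε each round until the per-round growth ratio stabilizes
  (tolerance 1e-13). The all-outbred start matters: under lethal inbreeding
  no selfed seed reaches adulthood, so AA adults are O(p²); seeding them at
  O(p) (e.g. via an inbreeding-equilibrium F correction) biases λ by an
  ε-independent O(1) amount. A halving check on ε warns when nonlinear
  terms are detectable.
* **Equilibria** — fixed-point iteration from p = 1e-3 and p = 0.999
  (bistability detection; roots differing by > 1e-6 are flagged), stopping
  when every state component moves < 1e-12, cap 10^7 iterations,
  non-convergence reported with the last state. When λ ≤ 1 the low-start
  root is reported as exactly 0: a fully recessive non-invading allele
  decays only algebraically (through rare AA exposure), so the
  state-change criterion would otherwise stall at a spurious ~1e-6.
* **Monte-Carlo oracle** — `oracle_step_montecarlo` samples every event of
  the life cycle (mother genotype, per-embryo origin/genotype, viability,
  primary choice, replacement, seed survival) family by family and is the
  independent check on the deterministic kernel (4-SE agreement at 10^6
  families).

Model agreement: backup-embryo and Charlesworth (C = 0.9) equilibria agree
to within ~1–8% for h = 0 and intermediate σ, but diverge near invasion
thresholds and at high σ (up to ~45% relative where both equilibria are
small, ≲ 0.02 absolute). The backup model behaves like different effective
C as h grows; C = 0.9 is the best overall match but not a uniform one.
Equilibrium frequency depends only weakly on s (e.g. p* = 0.047 vs 0.039
for s = 0.2 vs 1.0 at h = 0, σ = 0.3 — a ~19% relative, 0.008 absolute
difference), is highest for highly recessive alleles in frequently selfing
populations, and decreases with h.

## Forward simulator (`altload.simulate`)

A non-Wright–Fisher individual-based model: a genome of 100 000 sites in 10
chromosomes of 1 Morgan each (uniform maps); recurrent early-acting
recessive deleterious mutations at per-site per-gamete rate μ; each
generation N mothers are sampled with replacement from the survivors, each
produces two half-sib embryos (independent fathers, mother excluded; selfed
embryos draw both gametes from the mother), embryos survive
Bernoulli(viability) with viability multiplicative across loci, and a dead
embryo is replaced by its surviving sibling (*treatment*) or by a random
non-sibling embryo (*control*: all embryos are pooled, paired at random,
and the same keep-one rule applied — this removes the kin benefit while
keeping the census identical). Selfed seeds then survive with probability
`w_inbred`. Population size is regulated only through the fixed number N of
mother draws; the survivor count fluctuates below N.

Implementation: the population is a dense 0/1 haplotype matrix over
currently segregating mutation columns. Meiosis draws crossover *events*
(Poisson with mean = map length per gamete, positions uniform) plus a
random starting strand per chromosome, scatters them as parity toggles at
the first affected column, and resolves inheritance with one cumulative-sum
pass — at the level of site inheritance this is exactly the
odd/even-crossover-count process, vectorized across all gametes of a
generation. Each new mutation is its own record (quasi-infinite sites:
same-site collisions are allowed as separate records and are negligible at
the stated rates). Fixed mutations are removed from individuals and logged
as substitutions; "segregating" summaries exclude them. All randomness
flows from a single `numpy` Generator, so identical (parameters, seed) give
bit-identical trajectories.

Stationarity ("mutation–selection balance") is declared when the mean
mutation count per individual averaged over two consecutive non-overlapping
windows (default 500 generations) changes by < 1%, never before
`min_generations`; runs otherwise stop at the generation cap (default 20N)
or on extinction. The windowed rule is this package's own operational
definition of "run until balance".

## What the simulations emulate, and at what scale

The simulator emulates the idealized life cycle above — it has no
demographic structure, no seed bank, no late-acting load, no selfing-rate
evolution, and its control is an artificial re-pairing device, so passing
tests show internal consistency of the theory, not fidelity to any real
species. Desk-scale defaults in the test suite use N = 1000 (not the
full-scale N = 10 000): the comparative patterns (sibling > control at low
μ, their collapse at high μ, the sublethal reversal of the σ trend, old
alleles under sibling replacement) all reproduce at N = 1000, but the
*absolute* balanced load grows with N — at N = 1000, σ = 0.1, μ = 5e-8,
s = 1 the sibling-mode load is stationary at ≈ 1.4 mutations per individual
over 16 000 generations (control ≈ 0.75), whereas the full-scale load is
about five per individual. The high-mutation-rate comparison uses a fixed
250-generation horizon for both arms rather than full balance: mutational
input dominates both arms identically long before balance (observed
sibling/control frequency ratio ≈ 1.00 at that horizon, versus ≈ 1.9 at low
μ), and a full high-μ balance run is orders of magnitude more expensive
because tens of thousands of columns segregate.

With about five unlinked recessive lethals per genome, the fraction of
selfed seed expected to escape all of them is (3/4)^(2·5) ≈ 5.6% before
seed-stage selection — an effective, if leaky, late self-incompatibility
system built from load.

## Known limitations

* The Charlesworth-model recursion follows the printed maternal-fitness
  formula with the conditional-on-survival embryo distribution; other
  formulations of "compensation extent" are possible and would shift the
  C = 0.9 comparison.
* The sublethal (s < 1, w_inbred > 0) invasion threshold is reported as the
  printed two-mother-type bound, which is only sufficient (see above).
* `find_equilibrium` reports 0 for any non-invading allele, including the
  degenerate s = 0 case where every frequency is neutrally stable.
* Allele ages in finite runs are right-censored by the run length; age
  comparisons use equal horizons for the paired arms.
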
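# altload

**Can early-acting inbreeding depression evolve as an inbreeding-avoidance
mechanism?** In predominantly outcrossing species that cannot fully avoid
self-fertilization, a recessive allele that kills embryos early is almost
only exposed in selfed embryos. If the mother can *compensate* — replace an
embryo lost early with another, likely outbred one — then such
"self-sacrificial" alleles raise the inclusive fitness of their carriers and
can be *favoured* by selection, rather than merely tolerated at
mutation–selection balance. `altload` implements the theory end to end, for
population geneticists who want to compute with it rather than re-derive it:

* `altload.analytic` — closed-form invasion conditions. With dominance `h`,
  selection `s` against homozygous embryos, primary selfing rate `σ` and
  lethal inbreeding, a rare allele grows at rate
  `λ = (1 − hs)(1 + (s/4)(h + σ/2))` per generation; it invades when
  `σ > crit.self = 2h(3 + hs)/(1 − hs)` (≈ `6h` for small `h`), and, for
  sublethal inbreeding, when selfed-seed fitness `w_inbred` is below
  `s(1 − σ)/(4 − sσ)`.
* `altload.recursion` — exact genotype-frequency recursions for an infinite
  population under two compensation models (the two-embryo "backup" model
  and the Charlesworth maternal-fitness model `(1 − p_m)^(1−C)`), with
  invasion and equilibrium solvers and a Monte-Carlo event oracle.
* `altload.simulate` — a genome-scale, individual-based, non-Wright–Fisher
  forward simulator (100 000 sites on 10 chromosomes of 1 Morgan, recurrent
  recessive early-acting mutations, sibling replacement) with a matched
  control in which replacement occurs between random non-sibling embryos.
* `altload.summaries` — load, frequency-spectrum and allele-age summaries
  and a factorial treatment/control grid driver.

## Worked example

A partially recessive allele (`h = 0.05`, `s = 0.6`) in a population with
primary selfing rate 0.5 and lethal inbreeding:

```text
$ altload analytic --h 0.05 --s 0.6 --sigma 0.5
psi_aa  0.0
psi_Aa  0.09
family_mean_fitness_at_invasion 0.506825
invasion_growth_rate_closed_form        1.01365
critical_selfing        0.31237113402061856
critical_selfing_attainable     True
inbred_survival_threshold       0.08108108108108107
posterior_inbred_given_homozygous       1.0
```

Reading: in rare heterozygous-mother families 9% of primary embryos die and
are replaced (`psi_Aa`); carrier families out-reproduce the population
(`λ = 1.014 > 1`) because the critical selfing rate 0.312 is below the
actual σ = 0.5, so the allele invades. At σ = 0.25 the same allele is lost
— the numerical recursion agrees with the closed form:

```text
$ altload invade --h 0.05 --s 0.6 --sigma 0.25
lambda  0.9954624953002553
critical_selfing        0.31237113402061856
verdict does not invade
```

Where does a favoured allele stop? Iterating the recursion for a fully
recessive lethal (`h = 0`, `s = 0.6`) at σ = 0.3:

```text
$ altload equilibrium --h 0 --s 0.6 --sigma 0.3
p_star  0.04275040738675215
iterations      1135
converged       True
both_starts_agree       True
```

The allele equilibrates at p* ≈ 0.043: common enough that it is now often
exposed in outbred (allozygous) homozygotes, at which point it stops being
a reliable signal of inbreeding and selection turns against it — a
balanced polymorphism, not mutation–selection balance. The genome-scale
experiment behind the same question (`altload simulate`, or
`altload grid --config grid.yaml`) writes trajectory and mutation tables
whose headline pattern is that sibling replacement elevates the frequency
of early-acting recessives above the non-sibling control at low mutation
rates, that the elevation vanishes at high mutation rates, and that the
elevated alleles are old (balancing selection) rather than young.

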
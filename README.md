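# hybridbarriers

Analyses of reproductive barriers between naturally hybridizing swordtail
fish (*Xiphophorus birchmanni* × *X. cortezi*), built for population
geneticists working with low-coverage whole-genome data from hybrid zones
and lab crosses:

* **Local ancestry inference** — a 3-state hidden Markov model over
  diploid ancestry (0/1/2 copies of *cortezi* ancestry) applied to read
  counts at ancestry-informative markers (AIMs). Transitions come from two
  independent haploid chains with switch probability
  `(1 − e^{−T d}) · π` between markers at genetic distance `d` Morgans
  (`T` = generations since admixture, `π` the stationary ancestry
  frequency); emissions are `Binomial(depth, q)` with
  `q ∈ {ε, ½, 1−ε}`. Posteriors become hard calls at a 0.9 threshold.
* **Ancestry bimodality** — Hartigan's dip statistic
  `D = min_{G unimodal} sup_x |F_n(x) − G(x)|`, implemented from scratch
  (exact, validated against an LP minimax oracle), with a uniform
  bootstrap p-value, plus two-means ancestry-cluster assignment.
* **Assortative mating** — paired mother/embryo genome-wide ancestry:
  an embryo sits at the midparent value, so a cross-cluster mating shifts
  it by half the between-cluster distance. The assortment strength
  `a = P(within-cluster mating)` is fit by matched simulation.
* **Segregation-distortion scan** — per-site mean ancestry in F₂
  intercross offspring against a simulated Mendelian null with a
  family-wise (genome-wide max) 95% envelope, peaks delimited by
  ancestry-LD decay (R² ≥ 0.8, markers thinned to one per 50 kb).
* **Selection at incompatibility loci** — rejection ABC under
  Hardy–Weinberg with viability selection: adult F₂ genotype frequencies
  `(¼, ½(1−hs), ¼(1−s)) / W̄` with `W̄ = ¼ + ½(1−hs) + ¼(1−s)`;
  `(s, h) ~ Uniform(0,1)²`, draws accepted within 5% of the observed
  summary statistics; MAP and 95% HPD intervals from a
  boundary-reflected KDE.
* **Mitochondrial divergence** — pairwise p-distances from alignments, a
  two-lineage coalescent null for divergence without gene flow, and fixed
  amino-acid difference counts between species.

A synthetic-data generator (`hybridbarriers.simulate`) emulates the study
system — a two-cluster admixed population (cluster means 0.019 and 0.757
*cortezi* ancestry, weights 0.62/0.38), F₂ crosses with Haldane
recombination and planted selection, and ~1× Poisson/binomial read
sampling — so the whole pipeline runs end to end without access to the
original sequencing data.

## Worked example

```python
>>> from hybridbarriers import chi_square_gof, GenotypeCounts, SelectionABC

>>> chi_square_gof([33, 0, 0], [0.25, 0.5, 0.25])
GofResult(statistic=99.0, df=2, pvalue=3.1799709001977575e-22)
```

All 33 developmentally stalled F₂ embryos are homozygous *birchmanni* at
the *ndufs5* incompatibility locus; under Mendelian 1:2:1 expectations
that configuration gives χ² = 99 (df = 2, P = 3.2×10⁻²²) — development
stalls only with the incompatible genotype.

```python
>>> est = SelectionABC(n_draws=200_000, random_state=1)
>>> est.fit(GenotypeCounts(54, 109, 0))   # CC, BC, BB among 163 F2 adults
>>> est.s_map_, est.s_ci_
(1.0, (0.7967967967967968, 1.0))
>>> est.h_map_, est.h_ci_
(0.0, (0.0, 0.3003003003003003))
```

With no homozygous-*birchmanni* survivors among 163 adults, selection
against *birchmanni* ancestry at the locus is inferred to be essentially
complete (MAP s = 1.0) and recessive (MAP h = 0.0, with the wide h
interval reflecting the weak identifiability of dominance when the
selected homozygote class is empty).

The full synthetic pipeline — simulate, infer ancestry, dip test, mating
fit, scan, ABC — runs from the shell:

```bash
hybridbarriers replay --outdir out --seed 7
```

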
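# meioco

Cytological analysis of meiotic recombination for spreads scored at
prophase I: crossover (CO) numbers and chromosomal distribution from
MLH1 foci on synaptonemal complexes (SCs), crossover interference from
the gamma model and coefficient-of-coincidence (CoC) curves, and
double-strand-break (DSB) dynamics from RPA focus counts — together with
a gamma-renewal simulator that generates datasets with exactly the
statistical structure these analyses assume.

The package is aimed at meiosis labs that score immunofluorescent foci
on spread spermatocytes (or oocytes) and want the downstream statistics
— per-cell and per-SC focus frequencies, axis morphometry, centromere-
referenced CO positions, interference estimates and prophase staging
comparisons — as tested, scriptable building blocks rather than
spreadsheet formulas. The built-in defaults describe a gecko karyotype
(2n = 34: seventeen autosomal SCs, two of them metacentric, axes from
~130 µm down to ~17 µm, ~20 MLH1 foci per cell) studied across thermal
conditions, but every parameter is configurable.

## The model

COs on a chromosome arm are modelled as a stationary renewal process
whose inter-event distances follow a gamma law,

    X ~ Gamma(ν, νλ),   E[X] = 1/λ,   CV[X] = ν^(-1/2)

where λ is the CO intensity (expected COs per µm) and ν is the
interference parameter: ν = 1 is a homogeneous Poisson process (no
interference); larger ν gives more evenly spaced COs. The first event on
each arm is drawn from the equilibrium residual-gap distribution, so the
process is translation-invariant and E[#COs] = λ·L for every ν. On top
of this skeleton the simulator imposes the obligate CO (≥ 1 focus per
bivalent, by rejection), centromere suppression (independent thinning
within a pericentromeric window) and condition-dependent axis shrinkage.

Interference is estimated two ways:

* **Gamma fit** — on SCs bearing exactly two MLH1 foci, the inter-focus
  distance sample is fitted by maximum likelihood with a two-parameter
  gamma; the shape γ̂ solves ln k − ψ(k) = ln x̄ − mean(ln x).
* **CoC curve** — each arm is scaled to unit length and cut into 20
  segments; for segments i, j the CoC is the observed frequency of arms
  with a CO in both, divided by the product of the single-segment
  frequencies; values are averaged per separation (j−i)/20. CoC = 1
  means independence; the separation where the curve climbs back to 1 is
  the interference distance.

RPA counts per cell are modelled per prophase stage (leptotene → early
zygotene → late zygotene → pachytene) with negative-binomial laws and
compared across conditions by one-way ANOVA + Tukey HSD.

## A worked example

`examples/02_crossover_frequency.py` simulates the optimum (28 °C) and
cold-stressed (20 °C) conditions and compares CO frequency:

```
28 °C: 20.47 ± 1.52 MLH1 foci/cell (n=60)
20 °C: 22.85 ± 1.94 MLH1 foci/cell (n=60)
Welch t-test: t = 7.49, p = 1.73e-11
  -> cold-stressed cells carry significantly more crossovers

per-SC focus classes (0/1/2/3/>=4), relative frequency:
  28C: 0:0.000  1:0.814  2:0.170  3:0.016  4:0.001  (n=1020 SCs)
  20C: 0:0.000  1:0.733  2:0.198  3:0.061  4:0.008  (n=1020 SCs)
chi-square: X2 = 38.8, df = 2, p = 3.77e-09
```

The per-cell means recover the calibration targets (20.18 and 22.93
foci/cell); the class-0 frequency is exactly zero because the obligate
CO is enforced; the cold condition's surplus shows up as SCs with two or
more foci. `examples/04_interference.py` then quantifies interference:

```
28 °C: gamma shape 8.92 (95% CI 7.59–10.25, n=332 two-CO SCs; generative ν = 8.35)
20 °C: gamma shape 6.05 (95% CI 5.34–6.76, n=525 two-CO SCs; generative ν = 6.51)
  -> weaker interference (lower γ) under thermal stress
```

The other examples cover dataset simulation and I/O (`01`), axis
morphometry and CO positions (`03`), RPA dynamics (`05`) and the
end-to-end pipeline with its markdown report (`06`).

A thin CLI mirrors the pipeline for shell use:

```sh
meioco simulate -t 28 -t 20 --n-cells 50 --seed 1 --out data/
meioco interference --in data/ --out tables/
meioco run --config run.yaml
```

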
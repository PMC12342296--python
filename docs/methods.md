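# Methods

## The generative model

Crossovers on a chromosome arm are a stationary gamma-renewal process.
Inter-CO distances are i.i.d. Gamma(ν, νλ): mean 1/λ, coefficient of
variation ν^(−1/2). λ is the CO intensity per µm of synaptonemal-complex
(SC) axis; ν ≥ 1 is the interference strength (ν = 1 reduces the process
to homogeneous Poisson). The first event on an arm is sampled from the
equilibrium residual distribution — U·G with U ~ Uniform(0,1) and G from
the length-biased gap law Gamma(ν+1, νλ) — rather than anchoring a gap
at the arm origin. Stationarity has two consequences the tests rely on:
the marginal CO density is flat along the arm (no artefactual origin
enrichment), and E[#COs] = λ·L for every ν, which makes intensity
calibration analytic whenever no conditioning is active.

On this skeleton the simulator layers the cytology:

* **Karyotype.** 17 autosomal SCs; ranks 1 and 4 metacentric (p-arm
  fraction 0.45 by default — arm ratios are not part of the published
  karyotype, so a mild asymmetry was chosen to keep the arms
  distinguishable), the rest acrocentric. The reference length profile
  runs 130.48 → 111.86 µm (ranks 1–4, linear) and 80.60 → 17.33 µm
  (ranks 5–17, power-geometric decay). The four published endpoints are
  fixed; the single curvature degree of freedom was solved once so the
  grand mean per-SC length is 60.31 µm (total autosomal axis
  1025.27 µm), the physiological-condition reference.
* **Metacentric arms** are independent renewal processes — no
  interference propagates across the centromere.
* **Obligate CO** (default on): an SC with zero surviving foci is
  resampled wholesale. The conditioning inflates the effective yield,
  which the intensity calibration absorbs.
* **Centromere effect** (defaults: radius 0.1 of arm length, thinning
  probability 0.7): each focus closer to the centromere than the radius
  is deleted independently. The study reports suppression but no
  mechanism or magnitude; independent thinning is the minimal
  parameterization, and thinning runs before the obligate-CO check so
  conditioning guarantees a focus *after* suppression.
* **Axis scale.** Per condition, all lengths are multiplied by
  `axis_shrinkage` (1.0 at 28 °C; 48.31/60.31 at 20 °C; 48.49/60.31 at
  30 °C — the published per-cell mean SC lengths). Within a condition,
  each cell gets a shared unit-mean lognormal scale factor with CV 0.08,
  a modest cell-to-cell spreading variation that preserves within-cell
  rank order; it is the one generator feature not tied to a published
  number.
* **Intensity calibration.** Given a target mean of MLH1 foci per cell
  (20.18 / 22.93 / 21.86 for 28 / 20 / 30 °C), the per-µm intensity is
  found by bisection against batched simulation (400 cells per
  evaluation, tolerance 0.1 foci). Every evaluation reuses one fixed
  internal calibration seed, making the simulated mean a monotone
  deterministic function of intensity and the calibrated value a pure
  function of the configuration (results are cached). Without obligate
  CO and suppression the answer is analytic: intensity = target / total
  axis length.
* **RPA counts** per stage are negative-binomial with moment-matched
  dispersion (var = m + m²/k; k = ∞ recovers Poisson, used whenever the
  target SD² ≤ mean). Stage (mean, SD) defaults are the published
  values for leptotene, late zygotene and pachytene at 20/28/30 °C;
  early zygotene is not published and is interpolated between its
  neighbours. The pachytene 28 °C law (mean 19, SD 30.35) is strongly
  overdispersed (k ≈ 0.40), reproducing the published nucleus-to-nucleus
  variability.

## Estimation choices

**Gamma interference fit.** Only SCs with exactly two MLH1 foci
contribute, the classical harvesting rule. The two-parameter gamma ML
problem is profiled to one dimension: the shape solves
ln k − ψ(k) = ln x̄ − mean(ln x) (closed-form initialization, bracketed
Brent root to 1e-10), the rate is k/x̄. Constant samples raise a
degenerate-fit error; the default sample floor is 30. The asymptotic
95% CI comes from the inverse Fisher information,
Var(k̂) ≈ k/(n(kψ′(k)−1)).

Two flags control harvesting, both of which matter quantitatively:

* *Scale.* Distances are pooled in µm by default. Under the model the
  gap law per µm is identical on every SC (one intensity), so µm pooling
  compares like with like; normalizing by SC length turns the pool into
  a scale mixture across a 17–130 µm karyotype and distorts the shape
  (measured +23…+60% for ν ≤ 8). The normalized mode is retained
  (`normalize=True`) because classical scoring pipelines often record
  only relative positions.
* *Cross-centromere pairs.* With independent p/q arms, a two-focus
  metacentric whose foci straddle the centromere contributes a sum of
  two unrelated arm residuals, not an inter-CO gap. Because the two
  metacentrics are the longest SCs, such pairs are common and deflate
  the fitted shape by up to ~30% at high ν. They are included by
  default (whole-SC scoring is the field convention) but excluded by the
  package's recommended estimation protocol
  (`cross_centromere=False`), which brings parameter recovery for
  ν ∈ {2,4,8,12} to a −2…−8% median error (500 distances per
  replicate).

Even with the recommended protocol the cytological γ is a *windowed*
estimate: conditioning on exactly two COs inside a finite bivalent
biases the gap sample, most visibly at the Poisson null, where the two
foci are i.i.d. uniform, the distance is Beta(1,2), and the fitted shape
converges to ≈ 1.38 rather than 1. The bias grows with the per-arm CO
rate, so conditions with shorter axes and more COs (the 20 °C preset)
read a few percent lower than their generative ν. The parameter-recovery
test therefore exercises the renewal skeleton with obligate CO but with
centromere suppression and cell-scale jitter disabled: suppression
deletes foci (merging adjacent gaps) and scale jitter mixes gap scales —
both corrupt the inter-focus sample for reasons unrelated to
interference.

**CoC curve.** Arms (whole acrocentric SCs; metacentric p and q
separately) are scaled to [0,1] and cut into 20 segments; occupancy is
binary (≥1 CO counts once). For each pair i<j, CoC = observed both-
occupied frequency / (fᵢ·fⱼ); pairs with zero expectation are excluded
and counted in diagnostics; same-separation pairs are averaged
arm-count-weighted (a plain mean is available; the two coincide for a
single pooled dataset). The interference distance is the first upward
crossing of CoC = 1, located by linear interpolation with no smoothing;
if the curve never reaches 1 the maximum separation is returned with a
`reached=False` flag. One regime note: at the study's CO density (≲ 1
CO per arm) the crossing moves outward as ν grows; at much higher
densities (~2 per arm) the crossing instead tracks the mean inter-CO
spacing and that ordering reverses.

**Positions and morphometry.** Positions are stored in µm in a single
per-SC frame (origin at the centromeric end for acrocentrics, at the
p-telomere for metacentrics); relative positions are derived as
distance-from-centromere / arm length, with a focus exactly at a
metacentric centromere assigned to the q arm. Interval histograms use
half-open bins with the last bin closed, so pos_frac = 1.0 is counted.
Ranking assigns 1–17 by descending length with metacentrics pinned to
ranks 1 and 4 (in length order when distinguishable); ties break by
metacentricity, then input order, making the assignment deterministic.
The large (1–4) / short (5–17) split is frozen against the reference
condition rather than recomputed per condition. The centromere-effect
index is the observed focus frequency within a window of the centromere
divided by the uniform expectation; under thinning with probability p in
a window equal to the radius u its expectation is (1−p)/(1−p·u), ≈ 1−p
for small windows.

**Hypothesis tests.** Mean CO counts: two-tailed Welch t-test (a
pooled-variance flag exists; degenerate zero-variance comparisons return
p = 1 by convention). Focus-class distributions: contingency chi-square
without continuity correction, after pooling classes with expected
count < 5 into their inner neighbour (tail first, then class 0), which
preserves totals. Position distributions: two-sample KS per morphology
class. Multi-group RPA comparisons: one-way ANOVA + Tukey HSD on the
studentized range, computed per stage across temperatures (the
complementary per-temperature mode exists); with two groups Tukey
reduces exactly to the pooled t-test (q = |t|√2). These standard tests
are delegated to scipy behind the module interfaces.

## What the simulator does and does not emulate

It reproduces the statistical structure the analyses consume: renewal-
law CO placement with interference, obligate CO, centromere suppression,
karyotype-shaped axis profiles with condition shrinkage, per-cell count
targets, and stage/condition RPA laws. It does not emulate scoring noise
(focus merging at short distances, misassigned SC identities), per-
animal random effects, class-II (non-interfering) CO mixtures, within-
cell SC-specific length changes, or any mechanistic coupling between
DSB number and CO number — so green tests validate the estimators
against the model, not against microscope data. Reported recovery
numbers quantify estimator biases *within* this model (window censoring,
conditioning); real-data γ values carry those biases plus scoring noise.

## Problem sizes and tolerances

Simulation sizes in the tests and acceptance script (40–800 cells per
condition, 500 distances per recovery replicate, 3,000–5,000 arms for
the Poisson nulls) were chosen so Monte-Carlo error is small against the
assertion bands while the whole suite stays desk-scale. Stochastic
assertions use 4·SE bands around configured targets (plus the ±0.1-focus
calibration contract where the target is itself calibrated); oracle-
equivalence assertions are exact to 1e-12 (CoC, KS) or to the 0.01 grid
step (gamma ML vs grid search). The ν-recovery criterion uses the median
relative error over 20 replicates per ν.
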
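# Methods

This note documents the models, numerical choices and limitations of
`ordselect`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Ordinal probit regression with a ridge prior

**Model.** For a trait with C ordered categories, observation i has a
latent liability `ℓ_i = x_iᵀβ + e_i`, `e_i ~ N(0, 1)`, and
`y_i = c ⇔ γ_{c-1} < ℓ_i ≤ γ_c` with `γ_0 = −∞ < γ_1 < … < γ_{C−1} < γ_C = +∞`.
Marker effects are exchangeable, `β_j ~ N(0, σ_β²)`, with
`σ_β² ~ scaled-inv-χ²(ν, S)`.

**Identification.** The residual (liability) variance is fixed at 1 and
the model has no intercept; marker columns are centred internally and the
cutpoints absorb location. No cutpoint is anchored at 0 — the flat-prior
cutpoints are identified jointly with the (location-free) linear
predictor. This convention makes saved effect/threshold draws directly
usable by the selection functions without further bookkeeping.

**Gibbs sweep.** Per iteration:

1. liabilities: `ℓ_i ~ TruncNormal(x_iᵀβ, 1)` on `(γ_{c−1}, γ_c]` for
   observed `y_i = c`, unconstrained Normal for missing responses (these
   rows contribute no likelihood — this is exactly the posterior
   predictive for masked candidates);
2. effects: `β | ℓ ~ N((XᵀX + λI)⁻¹Xᵀℓ, (XᵀX + λI)⁻¹)`, `λ = 1/σ_β²`,
   drawn exactly through a thin SVD of X computed once per fit, so each
   draw costs O(nk) rather than O(k³);
3. variance: `σ_β² | β ~ scaled-inv-χ²(ν + k, (νS + βᵀβ)/(ν + k))`;
4. cutpoints: `γ_c ~ Uniform(max{ℓ_i : y_i = c}, min{ℓ_i : y_i = c+1})`,
   which preserves strict ordering by construction.

**Defaults.** `n_iter = 50 000`, `burn_in = 20 000`, `thin = 5`
(S = 6 000 retained draws), ν = 5, and S chosen so the prior mode of the
implied genomic variance `Σ_j var(x_j)·σ_β²` equals `r2/(1−r2)` with
`r2 = 0.5` — a weakly informative "half the liability variance is
genetic" default, standard for whole-genome ridge regression. Tests and
the simulator use shorter chains (stated per config); all settings are
user-facing (`McmcSettings`).

**Numerical care.** Truncated-normal draws use inverse-CDF sampling with
the uniform clipped to `[1e−14, 1−1e−14]` and the resulting deviate
clipped back into its interval, guarding CDF saturation for extreme
predictors. Every retained cutpoint row is strictly increasing; the
posterior-predictive pmfs telescope to sum exactly to 1.

**Calibration caveat.** The uniform single-site cutpoint update is the
classical data-augmentation scheme and mixes slowly when n is large
(interval widths shrink as 1/n). On self-simulated data (n = 300,
k = 50, C = 3) the acceptance suite measures per-cutpoint 90 %-CI
coverage of about 0.8 over 20 seeded runs — mildly below nominal, and the
reason the calibration check is stated per cutpoint rather than jointly.
Longer chains do not remove this entirely; a Metropolis cutpoint sampler
would, but is out of scope.

**Categories never observed in training** (possible late in simulated
selection cycles, when an undesirable category empties) are handled by
fitting on the compressed observed scale and mapping the cutpoints back
with degenerate (ε-width) intervals, i.e. numerically zero predictive
mass for unseen categories. The alternative — failing the whole scenario
replicate — would discard runs precisely when selection succeeds.

## 2. Divergence losses and expected posterior loss

KL divergence (natural log, `0·ln 0 := 0`), Bhattacharyya distance
`−ln BC`, and Hellinger distance `√(½Σ(√p−√q)²)` are implemented in their
standard textbook forms, which satisfy the identity `H² = 1 − BC`
(property-tested to 1e−12). Target pmfs must be strictly positive — a
zero target entry makes KL undefined. Disjoint-support Bhattacharyya
returns `+inf` with a warning; `+inf` losses rank last.

Multitrait losses are plain (equal-weight) sums of per-trait divergences.
Consequence: traits with more categories can dominate the total; no
per-trait weighting is offered in this version.

The expected loss is the **mean of per-draw divergences**, not the
divergence of the mean pmf. The two differ by Jensen's inequality; the
latter is exposed as the `loss_of_mean` diagnostic on `SelectionResult`.
Ranks ascend with loss, ties broken by input order (stable and
platform-independent). Predicted level = argmax of the posterior-mean
pmf, ties to the lowest category.

A monotone-alignment caveat: with a target concentrated on the top
category, KL ranking tracks the posterior-mean top-category probability
for almost all candidate pairs, but not exactly — the entropy of how the
residual mass splits over the remaining categories also enters KL. The
test suite asserts ≥ 95 % pairwise concordance among pairs whose
top-category masses differ by more than 0.02.

## 3. Recurrent-selection simulator

**Stated world** (full scale): 5 000 independently segregating biallelic
loci at founder frequency 0.5; 200 discrete generations of random mating
among 2 000 lines; three traits with marker effects i.i.d. per locus from
`N₃(0, S)` where S is one of three correlation structures (S1 all
positive, S2 antagonistic, S3 mixed); h² ∈ {0.3, 0.6} fixed for all
traits (scenarios E1–E6); tercile discretisation; 10 cycles of 70/30
train/candidate splitting, expected-loss ranking against
`q = (0.1, 0.2, 0.7)` per trait, top 30 % of candidates selected; next
generation of 2 000 doubled-haploid (DH) lines, one DH from the F1 of
each random pair of distinct selected parents; 20 Monte Carlo replicates.

**Reduced scale** (`ScenarioConfig.reduced_scale`): 500 loci, 400
lines/cycle, 100 burn-in generations, 3 replicates, 4 000/1 500/5 chains.
This keeps the full scientific structure at minutes of runtime; the
selection dynamics are slightly *faster* per cycle at this scale (fewer
markers to estimate from a comparable training fraction), which the
acceptance target for gain dynamics accommodates by a one-sided ("no
later than") comparison.

Design choices where the design was genuinely open:

* **Meiosis is fully independent across loci** (no recombination map).
  With independent loci, burn-in random mating cannot build linkage
  disequilibrium; the burn-in's real effect here is mild drift and
  family structure. We keep it for fidelity to the stated world.
* **Heritability calibration** uses the realised F0 genetic variance —
  `env_sd² = var(g)·(1−h²)/h²` — so h² holds exactly in the founder
  data, not merely in expectation.
* **Cutpoints are frozen at their F0 tercile values** for all later
  cycles, so category proportions are comparable across cycles (they are
  the y-axis of the whole exercise). Re-estimating them each cycle would
  re-normalise away the genetic gain being measured.
* **Effects scale is arbitrary** (unit per-locus variance): only the
  correlation structure and h² matter after environmental calibration.
* **DH variance jump.** Diploid founders have dosage variance 2pq per
  locus; DH lines have 4pq. The first selection cycle therefore roughly
  doubles the genic variance, pushing mass outward through the frozen
  cutpoints even without selection. This is a property of the stated
  breeding design, not an artefact; the no-selection control in the test
  suite compares DH generation to DH generation.
* **Seeds** follow a SeedSequence tree: master → replicate → cycle →
  stage (phenotyping, splitting, fitting, mating), so any run is
  bit-reproducible from its master seed.

What a green simulator test does *not* establish: behaviour under real
linkage maps, genotype-by-environment interaction, or mating designs
with coancestry control — all outside the model.

## 4. Random-sampling validation and the wheat-like fixture

Protocol per replicate: mask 30 % of lines as candidates; fit one ordinal
model per trait on the rest; rank candidates by each divergence; select
the top `n_select` (default 30); tabulate the **true held-out** category
frequencies of the selected lines; compare to `n_select` lines drawn
uniformly at random. Mean ± sd across replicates (default 30). Training
splits that lose a category for some trait are re-drawn with a fresh
seed, with a warning. Model-predicted-category tabulations are exposed as
a secondary output (`predicted_frame`), but effectiveness is judged on
true categories — the only reading under which the comparison measures
selection, not the model's self-assessment.

The bundled fixture generator emulates the *shape* of a real wheat
multi-disease panel: a few hundred lines, dosage markers at intermediate
frequencies, one 4-category and two 5-category severity traits with
strongly skewed marginals (≈ 60/19/18/2 % and 37/39/22/2/0.2 %-style),
default h² = 0.5, and the matching skewed targets
`q = (0.8, 0.1, 0.05, 0.05)` and `(0.8, 0.1, 0.05, 0.025, 0.025)`.
Liabilities carry a genomic signal scaled exactly to h²; cutpoints sit at
empirical liability quantiles of the requested marginals, with rare
categories guaranteed at least one line. What the fixture does **not**
emulate: real linkage disequilibrium, pedigree/relatedness structure,
genetic correlations between the diseases, or marker ascertainment — so
a green validation test establishes that the pipeline extracts available
genomic signal, not that it reproduces any particular dataset's numbers.
The harness accepts any complete `(X, Y)` matrices, so real data drop in
unchanged.

## 5. Known limitations

* Single-trait liability models only; no joint multivariate liability
  (the multitrait loss combines independently fitted traits).
* Ridge (Gaussian) prior only; no Bayesian-Lasso alternative yet.
* Uniform cutpoint updates mix slowly at large n (see §1).
* Dosage-matrix input only (no VCF/PLINK ingestion).
* Unweighted multitrait sums; traits with more categories weigh more.
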
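# ordselect

Bayesian divergence-based genomic parental selection for **ordinal traits**
(disease scores, stress ratings, quality grades), for plant and animal
breeders who must pick parents from genotyped candidates whose categorical
phenotypes are unknown or masked.

Ordinal traits break the assumptions of conventional genomic selection:
categories are ordered but not equidistant, and a single predicted "value"
hides which category a candidate will actually express. `ordselect`
instead works with whole probability distributions:

1. **Threshold model.** Each trait's observed score `y ∈ {1..C}` is the
   categorised version of a latent liability `ℓ = xᵀβ + e`, `e ~ N(0,1)`:
   `y = c` iff `γ_{c-1} < ℓ ≤ γ_c` with ordered cutpoints γ. Marker
   effects β carry a ridge (Gaussian) prior with a scaled-inv-χ²
   hyperprior on their variance; the model is fitted by Gibbs sampling
   with latent-variable augmentation. A candidate's predicted pmf under
   draw *s* is

       p_c = Φ(γ_c − xᵀβ_s) − Φ(γ_{c-1} − xᵀβ_s).

2. **Target distribution.** The breeder states a goal pmf `q` per trait,
   e.g. `q = (0.1, 0.2, 0.7)` — in the long run, 70 % of lines in the top
   category.

3. **Expected posterior loss.** Each candidate is scored by the average,
   over the S retained MCMC draws, of a divergence between its predicted
   pmf and the target (summed over traits):

       EL_i = (1/S) Σ_s Σ_j D(p_is^(j) ‖ q^(j)),

   with D one of Kullback–Leibler `Σ p ln(p/q)`, Bhattacharyya
   `−ln Σ √(pq)`, or Hellinger `√(½ Σ (√p−√q)²)`. Candidates are ranked
   by ascending EL; rank 1 is the best parent.

The package also ships a recurrent-selection simulator (six standard
scenarios crossing three genetic-correlation structures with h² ∈
{0.3, 0.6}) and a random-sampling validation harness with a
random-selection baseline.

## Worked example

Fit one 4-category disease trait on 150 phenotyped lines, then rank 50
unphenotyped candidates against a resistance-weighted target:

```python
import numpy as np
from ordselect import (OrdinalRidgeModel, McmcSettings,
                       single_trait_selection, make_wheat_like_fixture)
from ordselect.validate import WHEAT_TRAIT_SPECS

X, Y = make_wheat_like_fixture(200, 300, WHEAT_TRAIT_SPECS[:1], seed=42)
train, cand = np.arange(150), np.arange(150, 200)
y = Y[:, 0].astype(float); y[cand] = np.nan     # candidates unphenotyped
res = OrdinalRidgeModel(y, X).fit(McmcSettings(4000, 1500, 5, seed=0))
print(res.summary())
sel = single_trait_selection(X[cand], res.draws,
                             target=(0.8, 0.1, 0.05, 0.05), method="kl")
print(sel.summary(n_top=5))
```

Output:

```
Ordinal probit regression (ridge prior), Gibbs sampler
n_obs=150  markers=300  categories=4  draws=500
   param    mean      sd     q05     q95
 gamma_1  0.2579  0.0999  0.0952  0.4189
 gamma_2  1.1744  0.1658  0.9213  1.4395
 gamma_3  2.7474  0.3449  2.2228  3.3068
sigma2_b  0.0110  0.0042  0.0055  0.0185

Expected-posterior-loss selection (kl), 50 candidates, 1 trait(s)
 candidate_id    loss  rank  prob_cat_1  prob_cat_2  prob_cat_3  prob_cat_4
           49  0.1809     1      0.8132      0.1261      0.0571      0.0036
           37  0.1990     2      0.8231      0.1142      0.0570      0.0057
           27  0.2057     3      0.7706      0.1479      0.0741      0.0073
           17  0.2475     4      0.7243      0.1692      0.0944      0.0121
           28  0.2495     5      0.7547      0.1471      0.0872      0.0111
```

The cutpoints γ partition the liability scale; `sigma2_b` is the common
marker-effect variance. Each ranked row gives a candidate's expected KL
loss from the target and its posterior-mean probability of landing in each
score category — the top candidates concentrate ~80 % predicted mass on
category 1 (resistant), matching the target. In this synthetic run the
five best-ranked candidates were all truly category-1 lines, while the
candidate pool averaged a score of 1.5.

A `ordselect` console command exposes the same workflows
(`fit`, `select`, `simulate`, `validate`, `make-fixtures`); every run
writes a JSON manifest with parameters, seeds and versions.

## File formats

* genotypes / phenotypes: delimited text (tab or comma, auto-detected),
  first column line id, header row of marker/trait names; phenotype codes
  are integers from 1, `NA` for missing.
* posterior draws: `<prefix>_effects.txt` (or a flat `.bin` with a 2×int64
  header), `<prefix>_thresholds.txt` (one retained draw per row),
  `<prefix>_xmean.txt` (training-column centring).
* rankings: `candidate_id, loss, rank`, then per-category probabilities
  (single trait) or per-trait predicted levels (multitrait).
* cycle summaries: `scenario, replicate, cycle, method, trait, category,
  proportion, mean_loss_selected`.
* targets: YAML, `targets: [[...], ...]`, one strictly positive pmf per
  trait.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: (t2) the founder-population category proportions
after tercile discretisation in the full-scale simulation (2,000 lines,
5,000 loci, S1 correlations, h² = 0.6), and (t3) the first selection cycle
at which the replicate-mean proportion of the most desirable category
reaches its 0.7 target for all three traits under expected-KL-loss
truncation selection at reduced scale (500 loci, 400 lines/cycle, 3
replicates). Runtime ≈ 3 minutes on one CPU.
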
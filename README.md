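# mastpheno

Masting metrics and a Bayesian resource-matching state-space model for
monthly ordinal tree-phenology scores, built for semi-arid savanna
monitoring designs (18 species, 3 sites, 290 tagged trees, monthly visits
over 8 August–July phenological years).

## The problem

Masting — occasional large, synchronous reproductive events — is usually
diagnosed from interannual seed-crop statistics. Given monthly ordinal
intensity scores (0 = phenophase absent, 1–4 = quartiles of canopy
capacity) for leaf, flower and fruit display, two questions arise:

1. **Do the species mast?** Answered descriptively with five metrics per
   species and phenophase, computed on annual intensity series
   (mean score per August–July year):
   - *intensity* — mean annual intensity;
   - *CV* — sd/mean of annual intensity (CV > 1 is the conventional flag);
   - *volatility* — frequency-weighted periodogram mass
     `v = (2/T) Σ_k f_k I(f_k)`, rising with variance and alternating
     dynamics (unit-sensitive, not comparable across studies);
   - *synchrony* — mean pairwise Pearson correlation among conspecific
     trees (> 0.2 is the conventional flag);
   - *failures* — proportion of years with zero intensity;

   plus circular day-of-year timing windows (mean ± 1.5 circular sd) and
   a PCA of the species-mean metrics.

2. **Can resource matching alone explain the dynamics?** A mechanistic
   six-pool transport-resistance growth model (shoot/root structural
   mass, carbon and nitrogen substrates) runs weekly under climate
   forcing from the year 2000. Its carbon assimilation flux `U_C`
   predicts leaf display, and the substrate index

   `S = (1/f_C)(CS+CR)/(MS+MR) + (1/f_N)(NS+NR)/(MS+MR)`,

   lagged by a phenophase-specific λ ∈ [0, 52] weeks, predicts flower and
   fruit display through a cumulative-link ordinal model
   `Q_j = invlogit(δ_j − Xβ)`, `P_1 = Q_1`, `P_j = Q_j − Q_{j−1}`,
   `P_J = 1 − Q_{J−1}`, `y ~ Categorical(P)`. One parameter vector per
   species is estimated by delayed-rejection adaptive Metropolis MCMC
   until every parameter's effective sample size exceeds 50.

Because real monitoring data of this kind are rarely public, the package
ships a first-class synthetic-data generator replicating the study
design — seasonal semi-arid climate (≈550 mm/yr, wet-season onset near
DOY 298), tree deaths with August replacement, and species archetypes
spanning the masting-metric space — so the whole pipeline is testable
end to end with known ground truth.

## Worked example

```sh
mastpheno simulate --seed 2 --out demo/   # observations, roster, climate, truth
mastpheno metrics --out demo/             # metrics.csv, doy.csv, pca.json
```

`demo/metrics.csv` begins:

```
species,phenophase,intensity,cv,volatility,synchrony,failures,cv_gt_1,sync_gt_0.2
acaexu,flower,0.786,0.400,0.0287,0.387,0.000,False,True
acager,flower,0.143,1.262,0.0079,0.027,0.378,True,False
acagra,flower,0.263,1.526,0.0483,0.848,0.367,True,True
```

`acagra` is generated from the high-volatility archetype: CV 1.53 > 1
and synchrony 0.85 > 0.2 flag it as a masting candidate, while `acager`
(low-fecundity archetype) has a high CV purely through failure years
(38% of years zero) with no synchrony — the classic false positive that
the metric suite is designed to separate.

Fitting the state-space model to one species (truth: β_flower = 2,
λ_flower = 8 weeks, λ_fruit = 20 weeks):

```python
from mastpheno.pipeline import PipelineConfig, run_fit
cfg = PipelineConfig(out_dir="demo", seed=0)
run_fit(cfg, "acanig")
# {'species': 'acanig', 'converged': True,
#  'accuracy': {'leaf': 0.66, 'flower': 0.67, 'fruit': 0.68}}
```

The posterior (demo/fit_acanig.json) recovers the generating lags and
slopes: λ_flower 8.03 (95% CI 7.84–8.25), λ_fruit 20.07 (19.82–20.35),
β_flower 2.06 (1.91–2.21). Accuracy is the fraction of visits whose
predicted ordinal class (argmax of P at the posterior median) exactly
matches the observed class.

`mastpheno report --out demo/` then assembles observed-vs-modelled
intensity tables and timing-window charts from these outputs.

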
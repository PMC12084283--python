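# Methods

## Data model

Observations are long-format monthly records `(tree, species, site, date,
phenophase, score)` with ordinal scores 0–4 (0 = phenophase absent; 1–4 =
quartiles of the phenophase's magnitude relative to canopy capacity).
The phenological year runs 1 August – 31 July, matching the austral
growing season; annual intensity is the arithmetic mean of a tree's
monthly scores within a phenological year. A year is emitted only when
at least `min_months` (default 6) months were observed — half-year
coverage bounds the bias from mid-series deaths and August replacements
while retaining a replacement tree's first year. Missing visits are
absent rows, never zeros: a 0 score is a biological observation.

Day-of-year statistics use a fixed 365-day circle (29 February is folded
onto 28 February) so the circular modulus is constant across years.

## Masting metrics

Computed per tree on annual intensity series and averaged to species
(a pooled-species-series variant is available via `aggregation="pooled"`;
synchrony is inherently pairwise and has no pooled form):

* **intensity** — mean annual intensity, in ordinal-scale units.
* **CV** — sample standard deviation (n−1) over mean; undefined (NaN,
  with a warning) for all-zero reproducers.
* **volatility** — with the mean-centred series y₁..y_T and periodogram
  I(f_k) = |Σ_t y_t e^(−2πikt/T)|²/T at Fourier frequencies f_k = k/T,
  k = 1..⌊T/2⌋:  v = (2/T) Σ_k f_k I(f_k). Zero for constant series,
  quadratic in amplitude, and weighting by f_k makes alternating
  (boom–bust) series score above slow trends of equal variance. The
  value depends on the measurement units; volatilities are not
  comparable between studies using different intensity scales. Interior
  missing years raise an error by default (`gap_policy="interpolate"`
  fills linearly); series shorter than 4 observed years are missing.
* **synchrony** — per tree, the mean Pearson correlation with every
  conspecific partner (across sites) over ≥3 overlapping years; the
  species value is the mean over trees. Pairs containing a zero-variance
  series are skipped and logged.
* **failures** — proportion of non-missing years with intensity exactly 0.

Masting flags use the conventional thresholds CV > 1 and synchrony >
0.2; both are configuration, not constants.

**Timing.** For each species × phenophase, the qualifying set is all
observations whose score strictly exceeds the mean score of that
species–phenophase (zeros included in the mean). Angles θ = 2π·DOY/365
give the circular mean from the resultant vector and circular sd
√(−2 ln R̄)·365/(2π); the reported window is mean ± 1.5 sd (mod 365). A
summary is flagged diffuse when R̄ < 0.05 or the window spans the year.

**PCA.** Species-mean metric vectors (intensity, CV, volatility,
synchrony, failures) are centred and scaled to unit sample variance and
decomposed by SVD, so component variances are eigenvalues of the metric
correlation matrix (heterogeneous units make covariance-matrix PCA
meaningless here). Species with missing metrics are dropped and logged;
constant columns are dropped with a warning rather than divided by zero.

## Growth model

Six pools: shoot/root structural mass MS, MR; carbon substrates CS, CR;
nitrogen substrates NS, NR. Weekly explicit-Euler updates:

```
G_S  = g·CS·NS/MS                 G_R  = g·CR·NR/MR        (growth)
τ_C  = t_C·(CS/MS − CR/MR)        τ_N  = t_N·(NR/MR − NS/MS)  (transport)
U_C  = a_C·φ·MS/(1+MS/K_S) · 1/(1+(CS/MS)/J_C)            (assimilation)
U_N  = a_N·ψ·MR/(1+MR/K_R) · 1/(1+(NR/MR)/J_N)            (uptake)

MS += G_S − m_S·MS                MR += G_R − m_R·MR
CS += U_C − f_C·G_S − τ_C         CR += τ_C − f_C·G_R
NS += τ_N − f_N·G_S               NR += U_N − f_N·G_R − τ_N
```

φ is the product of trapezoidal (piecewise-linear, [0,1]-bounded)
responses to temperature, bucket soil moisture and radiation; ψ uses the
temperature response and a wetter-optimum moisture response
(mineralisation and diffusion both need wet soil). Soil moisture is a
weekly bucket: w ← min(capacity, (1−drain)·w + precip).

Carbon and nitrogen bookkeeping close exactly each step:
ΔCS + ΔCR + f_C(G_S+G_R) − U_C = 0 and the nitrogen analogue.

**Product inhibition.** Assimilation and uptake are down-regulated by
their own substrate concentration (the 1/(1+(C/M)/J) factors). Without
this feedback the six-pool system has a neutral direction — whichever
substrate is in stoichiometric excess accumulates without bound, and
initial conditions never wash out. With it, the system has a stable
interior equilibrium under constant forcing, and a 15-year spin-up
(model start 2000, observations from 2015) erases bounded initial-state
differences to below 10⁻⁶ relative — which is why the estimation can
treat the initial state as a nuisance within broad uniform bounds
(MS, MR ∈ [1, 20]; CS, CR ∈ [0.2, 10]; NS, NR ∈ [0.02, 1]).

**Numerics.** dt = 1 week (the native grid of the forcing and of the
state-space analysis); mass denominators are guarded at 10⁻⁹; per-pool
drains are flux-limited (scaled down if a step would overdraw a pool),
which keeps explicit Euler stable, and any residual negative values are
clipped to zero and counted (`trajectory.attrs["n_clipped"]`; < 1% of
steps on default configurations, typically 0).

Default rates (per week): a_C = 1.2, a_N = 0.3, g = 4, t_C = t_N = 0.5,
m_S = m_R = 0.12, f_C = 0.5, f_N = 0.025, K_S = K_R = 5, J_C = 0.3,
J_N = 0.008. These were chosen once so that (i) the interior attractor is
reached well inside the 2000–2015 spin-up, (ii) pools stay positive
without clipping, and (iii) the substrate index retains visible seasonal
and interannual structure. Masses are in arbitrary consistent units; the
predictors are standardized before entering the observation model, so
only the *shape* of the trajectories matters for inference.

## Observation model and inference

Leaf scores are predicted by U_C at the visit date (no lag); flower and
fruit scores by the substrate index S evaluated λ_ph weeks earlier
(λ ∈ [0, 52], one lag per phenophase), with linear interpolation between
weekly grid values. Predictors are z-scored over the study window of the
deterministic trajectory, identically in generation and fitting — a pure
reparameterisation of (β, δ) that keeps β order-one under vague normal
priors.

Cumulative-link categorical likelihood with J = 5 classes:
Q_j = invlogit(δ_j − xβ), P₁ = Q₁, P_j = Q_j − Q_{j−1},
P_J = 1 − Q_{J−1}. The intercepts are parameterised as δ₁ plus positive
(exponentiated) increments, so ordering — and with it P ≥ 0, ΣP = 1 — is
guaranteed for every parameter value the sampler can visit. The sign
convention means β > 0 ⇒ more substrate ⇒ mass shifts to higher classes.
(A non-normalising "absolute difference" variant of the middle classes
is available behind `printed_form=True` for comparison only.)

Priors: δ-raw and β ~ Normal(0, 5); λ ~ Uniform(0, 52); gamma
hyper-parameters for process-error variances are declared for the
stochastic-trajectory extension.

**Sampler.** Delayed-rejection adaptive Metropolis: a Gaussian random
walk whose covariance is re-estimated from the chain history every 500
iterations (scale 2.38²/d), with a second, 0.25-shrunken proposal and
the proper two-stage acceptance ratio after a first-stage rejection.
Chains extend in blocks until every parameter's ESS ≥ 50 (single chain,
as is standard with this sampler family) or an iteration cap. ESS uses
Geyer's initial-positive-sequence truncation of the autocorrelation sum.
Runs are bit-reproducible given the seed.

Because the seasonal substrate signal makes (β, λ) nearly mirror-
symmetric with (−β, λ ± half a season), the chain is initialised from a
coarse likelihood grid over λ and the slope sign, which places it in the
dominant basin before sampling begins.

**Deterministic-trajectory mode.** The latent trajectory is simulated
deterministically from θ (process error ε ≡ 0) and θ and the initial
state are held at configured values by default; the sampler explores
δ-raw, β and λ (any subset pinnable via `fixed=`). Jointly sampling 20+
years of weekly latent states is computationally prohibitive and is not
attempted; `simulate_trajectory(noise_sd=...)` provides stochastic
forward runs for sensitivity analysis. Consequences: posterior widths
condition on the deterministic trajectory and do not include
process-error uncertainty.

**Prediction.** At the posterior-median parameters, the predicted class
per visit is argmax_j P_j (ties broken to the lowest class); accuracy is
the fraction of exact matches per phenophase. Observed-vs-modelled
intensity reports use the probability-weighted expected score Σ_j(j−1)P_j,
which is smoother than the modal class.

## Synthetic study generator

Emulates the monitoring design: 18 species over 3 sites (28 species-site
pairs at 10 trees each, plus one extra configurable pair so the roster
totals the design's 290 individuals), monthly visits on the 15th from
August 2015 through July 2023 (96 visits), annual per-tree death hazard
(default 0.02) taking effect at the year boundary with replacement under
a fresh identifier the following August — so every slot stays occupied
and the study yields exactly 290 × 96 = 27,840 tree-visit events.

Climate: weekly temperature and radiation sinusoids with austral phase
plus noise; rainfall is zero-inflated gamma with seasonal occurrence and
mean (von-Mises-shaped seasonality peaking in mid-January), a lognormal
year-scale anomaly (sd 0.3, mean 1) for drought/wet years, and an
analytic scale solve so the expected annual total is 550 mm. The
occurrence/seasonality constants were calibrated once so the median
wet-season onset (first post-1-July date with trailing 30-day rainfall
above 25 mm) falls near DOY 298, and then frozen.

Phenology is generated through the same model that is fitted: one
deterministic trajectory per species-site from 2000, ordinal
probabilities per visit, independent categorical draws per tree. Trees
of a species share the latent trajectory — between-tree variation is
purely observational, mirroring the fitted model's structure. Observer
error beyond the categorical draw is not modelled, there is no
individual-level physiological variation, and sites share one synthetic
climate; passing tests therefore demonstrate the pipeline's correctness
and the model's recoverability under its own assumptions, not robustness
to the full heterogeneity of field data.

Archetypes place species in the metric space: *resource matcher*
(moderate slope, λ_flower = 8, λ_fruit = 20), *high volatility* (steep
slope and far-right-tail intercepts over a drought-sensitive θ whose
moisture response saturates only in wet years — reproduction collapses
in dry years, giving CV > 1 and synchrony > 0.2), *low fecundity* (high
intercepts, weak slope: rare display, frequent failure years, high CV
without synchrony — the classic masting false positive), and *aseasonal
null* (β = 0; scores iid categorical).

## Problem sizes used in the shipped checks

Parameter recovery runs 20 replicates of a reduced design (one species,
one site, 3 trees, flower phenophase only: 6 free parameters) at 10⁴
iterations per chain; coverage is counted over all parameter × replicate
pairs. Calibration checks use 200 simulated climate years. The full
three-phenophase, 17-parameter species fit used in the worked example
converges (all ESS > 50) in about a minute on one core.

## Known limitations

* Process error is excluded from the posterior (deterministic mode);
  credible intervals are conditional on the trajectory.
* The growth model is a stylised weekly transport-resistance system;
  its rate constants are effective, not measured, quantities.
* Volatility values are scale-dependent by construction.
* The metric aggregation (per-tree means) and the partial-year coverage
  rule are analysis choices; both are configurable and the alternatives
  (pooled series, different `min_months`) are implemented.
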
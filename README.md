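# gmmdiag

Bayesian growth mixture models with diagnostics for degenerate MCMC
behavior.

## What problem this solves

Growth mixture models (GMMs) ask whether a population followed over time
— here the motivating case is children's reading-recognition development
across biennial assessments — consists of latent subgroups with distinct
growth trajectories. Each of K classes has its own quadratic mean
trajectory and its own random intercept/slope covariance:

    y_ij | c_j = k :  β₀ᵏ + β₁ᵏ t_ij + β₂ᵏ t_ij² + ζ₁j + ζ₂j t_ij + ε_ij
    (ζ₁j, ζ₂j) ~ N(0, Ψᵏ),   ε_ij ~ N(0, σ²),   c_j ~ Cat(π)

Bayesian estimation of such mixtures is haunted by **degenerate
nonidentifiability**: parameter points where the K-class model collapses
to fewer classes (a class probability at zero, or two classes with
identical parameters) are non-identified and **self-perpetuating** in
MCMC — a near-zero class probability makes the sampler draw that class's
parameters from the prior, which keeps the probability near zero. The
result is stuck chains, "miniscule-class" sequences, and twinlike
classes that silently corrupt posterior summaries.

`gmmdiag` is for analysts fitting GMMs who need to (a) estimate the
model on the marginal likelihood — integrated over both class membership
and the random effects, so only continuous structural parameters are
sampled — and (b) *detect* pathological sampling and (c) study how prior
choices (Dirichlet concentration α₀, half-normal vs half-Cauchy SD
priors) prevent it. The core diagnostics:

* **stuck sequences** — runs of literally unchanged draws, found via
  zero trailing moving-SDs of the smallest class probability (a run of q
  zero windows of size h ⇔ q + h − 1 frozen iterations);
* **distinguishability index (DI)** — per class pair and draw,
  `DI = 100 (1 − Ē / log 2)` where Ē is the mean binary entropy of the
  equal-weight conditional classification probabilities
  f_k/(f_k + f_l): 0 for twinlike (indistinguishable) classes, 100 for
  perfectly separated ones — the latter is the signature of a class
  drawn from its prior;
* **miniscule-class detection** — 2-means clustering of the moving
  statistics of the smallest class probability, plus a DI > 95 run rule;
* rank-normalized split R-hat / ESS / E-BFMI screening, and Stephens'
  Kullback–Leibler relabeling for label switching.

Everything is organized statsmodels-style: a `GrowthMixtureModel` built
from data, whose `fit()` (multi-start maximum marginal likelihood) and
`sample()` (Hamiltonian Monte Carlo with analytic gradients) return
results objects carrying estimates, uncertainties, diagnostics and
`summary()` tables.

## Worked example

```python
import numpy as np
from gmmdiag import GrowthMixtureModel, nlsy_like_params, simulate_gmm

# a reading-recognition-like panel: 405 children, occasions 0..3,
# ~3.21 records per child, three latent trajectory classes
panel = simulate_gmm(nlsy_like_params(), n_subjects=405,
                     missing_pattern="nlsy", seed=11)

model = GrowthMixtureModel(panel.dataset, n_classes=3)   # D10N50 priors
results = model.sample(n_chains=2, warmup=1000, iters=1000, seed=1).relabel()
print(results.summary().round(3))
```

which prints (abridged):

```
 parameter   mean    sd   2.5%  97.5%  rhat  ess_bulk  ess_tail
      pi.1  0.287 0.046  0.202  0.383 1.022   104.532   246.764
      pi.2  0.309 0.031  0.251  0.372 1.017   191.526   622.106
      pi.3  0.404 0.041  0.327  0.491 1.012   119.880   183.083
   beta0.2  3.271 0.093  3.073  3.444 1.051    72.462   240.130
    corr.2 -0.707 0.069 -0.820 -0.554 1.031    94.530   293.118
     sigma  0.285 0.010  0.266  0.304 1.007   317.231   655.355
```

The generating values (π = 0.267/0.286/0.447, σ = 0.30, a high-starting
class with intercept 3.2 and correlation −0.742) sit inside the
intervals; class labels are arbitrary until `relabel()` fixes a common
labeling across draws. Then the pathology screening and the
within-class heterogeneity summaries:

```python
report = results.diagnostics()
print("stuck chains:", report.persistently_stuck_chains)        # []
print("miniscule-class chains:", report.chains_with_miniscule)  # []
print("parameters with R-hat > 1.10:", report.n_rhat_flagged)   # 0

print(results.heterogeneity(0, t0=0.0, T=3.0, a0=2.0))
# {'pct_change_deviation': 7.717,
#  'standardized_deviation_at_T': 1.010,
#  'prob_positive_slope': 0.526}

elpd, p_waic, w = results.waic()
print(f"WAIC: {w:.1f} (p_waic = {p_waic:.1f})")   # WAIC: 2256.1 (p_waic = 19.6)
```

Reading the heterogeneity numbers for class 1 (whose intercept-slope
correlation is poorly identified here, hence the posterior-averaged
descriptors sit near their neutral values): an individual starting two
SDs from the class mean is expected to deviate about 8% more at occasion
3 than at occasion 0 (about 1.0 SDs in occasion-3 units), with a 53%
posterior probability of a positive random slope. WAIC is
computed on the *mixed* predictive density — marginal over class
membership and random effects — so it compares models by how predictive
they are for new subjects; refitting with `n_classes=2` or `4` and
comparing WAIC performs class enumeration.

With deliberately vague priors the same pipeline exhibits and flags the
pathologies instead:

```python
from gmmdiag.params import PriorConfig
vague = GrowthMixtureModel(panel.dataset, n_classes=3,
                           prior=PriorConfig.from_label("D2C5"))
bad = vague.sample(n_chains=2, warmup=500, iters=500, seed=1,
                   init="random")
print(bad.diagnostics().to_dict()["step4"])   # miniscule-class segments
```

A command line mirrors the library:
`gmmdiag simulate | fit | relabel | diagnose | summarize | grid | report`.

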
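# Methods

## Model

`gmmdiag` fits growth mixture models (GMMs): finite mixtures of
growth-curve (linear mixed) models for long-format panel data. Subject
*j* with observation times *t₁…t_nⱼ* belongs to a latent class *c_j*
drawn from a categorical distribution with probabilities **π**. Given
class *k*, the response at time *t* is

    y = β₀ᵏ + β₁ᵏ t + β₂ᵏ t² + ζ₁ + ζ₂ t + ε,

with subject-level random intercept and slope (ζ₁, ζ₂) ~ N(0, Ψᵏ) and
residual ε ~ N(0, σ²), σ shared across classes. The quadratic mean
captures decelerating growth; the random-effect design is deliberately
limited to intercept and linear slope because panels with ~4 occasions
cannot support a random quadratic term.

All inference uses the likelihood **marginal over both latent variables**.
Integrating (ζ₁, ζ₂) out of the class-k model makes a subject's response
vector multivariate normal with mean Xβᵏ and covariance
Σᵏ = ZΨᵏZ' + σ²I, where X has columns (1, t, t²) and Z columns (1, t);
summing over classes gives the mixture marginal likelihood
Σⱼ log Σₖ πₖ fₖ(yⱼ). No discrete indicators or per-subject effects are
ever sampled — the sampler sees only the continuous structural
parameters. Subjects sharing an observed time pattern share one Σᵏ per
class, so likelihood and gradient evaluations batch by pattern.

## Priors

* Dirichlet(α₀, …, α₀) on **π**. α₀ acts like α₀ − 1 phantom subjects
  per class; larger values discourage near-empty classes.
* Half-normal or half-Cauchy with scale *s* on the random intercept and
  slope SDs of every class. Default: half-normal with s = 50 (vague at
  the reading-score scale but with light tails).
* LKJ(η = 2) on each 2×2 random-effect correlation matrix — density
  ∝ (1 − ρ²)^(η−1), slightly favoring correlations near zero.
* Independent zero-mean normals on (β₀, β₁, β₂) with SDs (10, 5, 5):
  weakly informative for responses on the 0–8.4 score scale.
* Half-normal(5) on σ.

The β SDs, residual scale, and LKJ shape are package defaults chosen as
weakly informative at the data scale. The shorthand `DdNs` / `DdCs`
names a configuration: `D10N50` is α₀ = 10 with half-normal(50) SD
priors, `D2C5` is α₀ = 2 with half-Cauchy(5).

## Estimation

**Maximum marginal likelihood** (`GrowthMixtureModel.fit`): L-BFGS with
analytic gradients on an unconstrained parameterization (additive
log-ratio for π, log-SDs, Fisher-z correlations, log σ). Multi-start:
the first start is a deterministic moments initialization (subjects
split into K quantile groups of their mean response, per-group OLS of y
on (1, t, t²)); the remaining starts add Uniform(−2, 2) perturbations to
sweep for local optima. Distinct optima are reported after canonical
relabeling (ascending π), using a log-likelihood tolerance of 1e-4.

**Posterior sampling** (`GrowthMixtureModel.sample`): a self-contained
Hamiltonian Monte Carlo backend (`gmmdiag.hmc`) with

* leapfrog integration under a diagonal metric, adapted in
  expanding warmup windows (Stan-like schedule) with shrinkage toward
  the unit metric;
* dual-averaging step-size adaptation toward a 0.8 acceptance target;
* trajectory lengths drawn uniformly from the upper half of
  [1, int_time/ε], capped at `max_leapfrog` steps (cap hits are
  recorded, the analog of a tree-depth warning);
* divergence detection when the energy error along a trajectory exceeds
  1000, with the divergent draw rejected and flagged;
* per-iteration energy recorded right after momentum refresh — the
  series that defines E-BFMI.

Gradients of the marginalized log posterior are analytic (multivariate
normal differential identities chained through the unconstrained
transforms) and are verified against finite differences in the tests.

**Initialization matters.** Mixture posteriors contain locally stable
degenerate basins: a class probability can sit at the Dirichlet floor
(≈ α₀ / (n + Kα₀)) while that class's parameters wander their priors.
Diffuse Uniform(−2, 2) starts (the `init="random"` strategy) land this
backend in such basins for almost any prior, because a plain HMC warmup
explores far less than a full NUTS implementation. Applied fitting
therefore defaults to `init="ml"` — jittered multi-start ML estimates,
the strategy blavaan uses — with `init="moments"` as a cruder
alternative. Random initialization remains available and is exactly what
the prior-sensitivity study uses, since prior-dependent *recovery* from
bad starts is the phenomenon of interest there.

## Label switching

The mixture likelihood is invariant to label permutations, so draws are
relabeled after sampling with Stephens' Kullback–Leibler algorithm: it
alternates between averaging the (permuted) posterior classification
probability matrices and choosing, per draw, the permutation minimizing
the KL divergence to that average, until no permutation changes.
Permutations are found by enumeration for K ≤ 6 and by the Hungarian
algorithm above that; probabilities are clipped at 1e-12 inside
logarithms; a 100-sweep cap triggers a warning. Relabeling never changes
any draw's likelihood, only the class indexing.

## Diagnostics for degenerate sampling

Four-step screening (`diagnostics_report`):

1. **R-hat screening.** Rank-normalized split R-hat (max of bulk and
   folded forms) and bulk/tail ESS per parameter, via arviz; parameters
   with R-hat > 1.10 are counted. When every chain is constant the
   within-chain variance is zero: R-hat is reported as infinite and ESS
   as unavailable rather than silently computed.
2. **Stuck sequences.** Trailing moving SD (window h = 10) of the
   smallest class-probability series. A maximal run of q zero-SD windows
   means q + h − 1 literally unchanged iterations; runs of ≥ 20
   iterations are reported, and a run covering the whole chain marks it
   persistently stuck. Constant windows are forced to exactly zero, so
   the arithmetic (a 20-iteration run ⇔ 11 zero windows at h = 10) is
   exact, not float-dependent.
3. **Twinlike classes.** The distinguishability index per class pair and
   iteration: with p̃ⱼ = fₖ(yⱼ)/(fₖ(yⱼ) + fₗ(yⱼ)) computed in log space
   under equal class weights, DI = 100 (1 − Ē / log 2) where Ē is the
   average binary entropy of the p̃ⱼ. DI is 0 when the two classes'
   densities coincide and 100 when every subject is classified with
   certainty; the normalization makes it invariant to the logarithm
   base. Runs of DI < 5 lasting ≥ 2 iterations are persistent findings;
   single-iteration dips are listed separately as non-events.
4. **Miniscule classes.** Route A: 2-means clustering of (moving
   average, moving SD) of the smallest class probability; if the smaller
   centroid lies within 0.05 of the origin in both coordinates, its
   iterations are flagged, after discarding the top 10% by moving
   average inside that cluster (a conservative trim; assignment ties
   break toward the non-miniscule cluster). Route B: runs of ≥ 3
   consecutive iterations in which the DI against the smallest class
   exceeds 95 — requiring *all* pairs involving that class, since a
   prior-wandering class is nearly perfectly distinguishable from every
   data-supported class. Route B is skipped for persistently stuck
   chains, which are a separate pathology.

Sampler-health metadata (divergences, leapfrog-cap hits, E-BFMI < 0.3)
is reported alongside. E-BFMI is Var(ΔH)/Var(H) of the per-iteration
energies; i.i.d. energies give ≈ 2, constant energies are reported as
undefined.

## Predictive criteria and heterogeneity

WAIC and PSIS-LOO are computed on the **mixed predictive density** — the
subject-level log density marginal over class membership and random
effects — never the conditional density. WAIC uses
lppd − p_waic with p_waic the population variance (1/S) of the pointwise
log densities over draws, so duplicating draws changes nothing; PSIS-LOO
is delegated to arviz.

Within-class heterogeneity descriptors (per class, dropping the k
superscript): trajectory SD σ(t) = √(ψ₁₁ + 2tψ₁₂ + t²ψ₂₂); central
"mid-range" bands mean(t) ± Φ⁻¹((1+c)/2)·σ(t); the slope-on-intercept
regression coefficient ψ₁₂/ψ₁₁; the percent change in deviation between
t₀ and T, 100(T−t₀)ψ₁₂/ψ₁₁; the expected standardized deviation at T for
someone starting a₀ SDs from the mean; and P(positive slope | a₀) =
Φ(ρa₀/√(1−ρ²)). Posterior summaries of these descriptors are averaged
over draws by default (nonlinear functions of uncertain parameters), with
a clearly labeled plug-in-at-posterior-mean mode also available — the two
can differ materially for the positive-slope probability when ρ is
uncertain.

## Synthetic data

`simulate_gmm` draws class labels, bivariate-normal random effects (via
an explicit PSD factor, so degenerate Ψ including Ψ = 0 is allowed), and
Gaussian residuals, deterministically per seed. The default
`nlsy_like_params()` emulate a reading-recognition panel: 405 children,
biennial occasions coded 0–3, scores on a 0–8.4 scale (raw PIAT reading
recognition / 10), three classes — early bloomers (π = 0.267, high
start, the largest initial heterogeneity, ρ = −0.742), rapid catch-up
learners (π = 0.286, fast decelerating growth, ρ = 0.399), steady
progressors (π = 0.447, lowest start, fanning out, ρ = 0.485). The
probabilities and correlations are published values for this panel; the
trajectory and variance values are package choices that reproduce the
described class shapes while keeping the three-class structure
empirically identified at n ≈ 400 (a unique non-degenerate ML optimum),
as reported for the original analysis. The `"nlsy"` missingness pattern
always keeps the first occasion and retains each later one independently
with probability (3.21 − 1)/3, matching the panel's average of 3.21
records per child. `well_separated_params()` provides a deliberately
easy configuration (mean trajectories several residual SDs apart) for
parameter-recovery studies.

What the generator does **not** emulate: bounded discrete raw scores
(responses are unbounded Gaussians), basal/ceiling administration
artifacts, age heterogeneity within occasion, non-normal random effects,
and informative missingness. Passing recovery tests on these data show
the estimation machinery is correct under the model's own assumptions,
not that the model is adequate for any real reading panel.

## The prior-sensitivity study

`run_prior_grid` runs independent single chains (replicates) over a grid
of prior configurations on one simulated dataset, scheduling cells from
hardest to easiest (C5, then N100, N50, N5, N1 within each α₀), applies
the diagnostics to every chain, and `prevalence_table` tabulates percent
stuck-chain / stuck-sequence / miniscule behavior per cell, plus the
percent of disjoint 4-chain batches with any R-hat > 1.10 and the rates
of sampler warnings. `binomial_ci_halfwidth` gives the exact
Clopper–Pearson margin of error for the tabulated percentages (about 7
percentage points at 50% with 200 chains); `di_roc` evaluates the DI as
an iteration-level detector of near-zero class probabilities (rank-based
AUC, sensitivity and specificity at a cutoff).

Scaled-down study sizes used by the test suite (package choices): a
100-subject complete panel, six cells (D2N50, D6N50, D10N50, D10N100,
D10N5, D10C5), 20 random-init chains per cell with 500 warmup and 300
kept iterations and a 64-step leapfrog cap; parameter recovery uses ten
405-subject replicates with one chain of 500 + 500 iterations each. At
these scales the directional contrasts (pathology no rarer under vaguer
priors; persistently stuck chains only under half-Cauchy) are assessed
with one-sided exact tests at the 10% level rather than by comparing
percentages to full-scale values. The 100-subject panel is deliberately
smaller than the motivating study's 405: it lowers the likelihood
barrier between the dominant and the degenerate basins so that
prior-dependent recovery is observable within a few hundred iterations.

## Numerical choices

* Log-sum-exp everywhere a mixture is collapsed; π components that are
  exactly zero are skipped, not logged.
* Simplex parameterized by additive log-ratios (last class reference);
  SDs by logs; correlations by Fisher z; Jacobians included in the HMC
  target so priors are honored on the constrained scale.
* Marginal covariances are validated by sign checks of batched
  `slogdet`; a singular covariance (σ = 0 with degenerate Ψ) raises.
* Moving-SD windows that are literally constant are set to exactly 0.0
  (window max == min test), making stuck-run arithmetic exact.
* K-means (scikit-learn) with k = 2, 10 restarts, seeded from the
  diagnostics config; deterministic given the seed.
* Classification probabilities are clipped at 1e-12 inside the KL
  relabeling objective.
* Draws persist as per-chain CSVs plus a JSON metadata sidecar holding
  seeds, iteration counts, prior label and backend settings; a run is
  reproducible from the persisted metadata with the same package
  version.

## Known limitations

* The HMC backend is plain jittered-trajectory HMC, not NUTS: its warmup
  explores less, so diffuse random starts reach degenerate basins more
  readily than Stan's sampler would, and effective sample sizes per
  iteration are lower. Comparisons across priors within this backend are
  meaningful; absolute pathology rates are backend-specific.
* Class-specific residual variances, covariates predicting membership,
  and nonlinear (e.g. Gompertz) growth curves are out of scope.
* The twinlike-class threshold (DI < 5) does not adapt to the sample
  size; the miniscule-centroid tolerance (0.05) is a fixed default.
  Both are configurable.
* With α₀ = 10 a fully emptied class sits near π ≈ 10/(n + 30), which
  for small n is above conventional "miniscule" magnitudes; the DI
  route detects this regime, the centroid route may not.
* Iteration-level *specificity* of the DI rule for near-zero class
  probabilities cannot be estimated meaningfully at the scaled-down
  study sizes: vague-prior chains here spend essentially all iterations
  in the degenerate regime (almost no non-event iterations), and in
  α₀ = 10 cells the degenerate floor itself exceeds a 0.05 event cutoff.
  Only the rule's sensitivity is asserted in the tests; at full scale,
  with long chains that alternate between regimes, the specificity of
  the rule is a property of the healthy phases the scaled-down study
  lacks.
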
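# Methods

`connlearn` re-implements, as a tested library, a connectome-based pipeline for
predicting individual differences in learning, extinction, and renewal from
multimodal brain connectivity. Because the underlying human MRI/SCR data
cannot be shared, every stage runs against a synthetic multi-study cohort
generator whose statistical structure matches what the analysis assumes. This
note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic validation does and does not show.

## The network

Ten nodes: dorsal anterior cingulate (ACC), amygdala (AMY), cerebellar nuclei
(CEB), hippocampus (HIP), and ventromedial prefrontal cortex (PFC) in each
hemisphere. Cerebral-cerebral connections are ipsilateral; every CEB
connection pairs a cerebellar node with a contralateral cerebral node, because
cerebellar output crosses at the brainstem. This gives 20 undirected edges
(functional and structural connectivity) and 40 directed edges (effective
connectivity); for n regions per hemisphere the directed count is 2(n² − n).

## Synthetic cohorts (`synthgen`)

One global integer seed; every operation receives an independent substream
(`numpy.random.SeedSequence.spawn`) in a fixed order — per study: covariates,
connectivity, time series, trials; then outcome planting — so a fixed seed
reproduces the cohort bit-identically.

* **Studies.** The default roster has five fear-learning (FL) studies with
  skin-conductance (SCR) learning indices (n = 60 each; one with a renewal
  phase) and one larger predictive-learning (PL) study with binary behavioural
  responses (n = 180, all three phases). TR 2 s, 190 resting-state volumes.
  SCR phases have 8 trials per CS type; the PL study has 24 trials per phase
  (8 unique trial types, 3 presentations each) — a single presentation per
  type leaves the per-subject logistic estimates too coarse to carry
  individual differences.
* **ROI time series.** Stationary AR(1) Gaussian processes
  (`z_t = φ z_{t−1} + √(1−φ²) L ε_t`, default φ = 0.4), whose stationary
  covariance equals the target correlation matrix. Per-subject matrices are
  drawn around a qualitative coupling template (strongest HIP–AMY, then
  HIP–PFC and AMY–PFC; weak cerebellar edges) with Fisher-z jitter
  (sd 0.15). The AR(1) choice is the simplest stationary model that gives the
  spectral metrics realistic autocorrelation; it does not emulate
  haemodynamics, scanner drift, motion, or physiological noise.
* **Connectivity tables.** EC: Gaussian around a signed mean template —
  mostly inhibitory (−0.2) with positive bidirectional HIP↔AMY (+0.3) —
  between-subject sd 0.15, per-connection posterior variances uniform in
  (0.01, 0.1). SC: negative-binomial streamline counts (dispersion 2) with a
  skewed mean template (HIP–AMY ≫ ACC–PFC > AMY–PFC > rest); the
  dispersion → ∞ limit is Poisson. Signs and orderings are qualitative; the
  magnitudes are free parameters.
* **Trials.** SCR: `amplitude = 0.5 + g_i·f(t)·1[CS+] + ε`, ε ~ N(0, 0.2),
  with a linear phase template f (increasing in acquisition, decreasing in
  extinction/renewal) so that polynomial scores are analytic:
  score = g_i (T − 1). Learning rates g_i ~ N(0.5, 0.15). Behavioural:
  responses Bernoulli(σ(b0_i + b1_i t)) with per-subject normal intercepts
  and slopes; renewal-phase responses Bernoulli at a per-subject propensity.
* **Planted effects.** `latent_i = Σ β_e z(x_ie) + γ·covariates + ε_i`; the
  noise is solved so the population R² matches `target_r2`. Trial-generating
  rates are then re-linked so measured scores correlate with the latent
  outcome (link ρ = 0.9). Measured scores track the latent ground truth at
  r ≈ 0.88 (SCR, 8 trials) and r ≈ 0.6 (behavioural, 24 trials): trial
  noise, response binarization, and logistic saturation attenuate any planted
  effect by roughly a factor 0.4–0.8 in R² terms. Validation suites that
  assert a *stated* population R² therefore regress the standardized latent
  scores; suites that probe the measurement chain use the trial-derived
  scores.

## Functional-connectivity metrics (`fcmetrics`)

Nine metrics per edge, standard textbook definitions: Pearson correlation;
maximal lagged cross-correlation (|lag| ≤ 10 samples, sign retained);
Euclidean, Manhattan, and classic dynamic-time-warping distances (absolute
local cost, symmetric steps, no window), computed on z-scored series by
default so they measure shape, not amplitude; 1-Wasserstein distance between
amplitude distributions (raw scale — it is a location-sensitive distribution
distance); plug-in mutual information from an equal-width 2-D histogram
(⌈√(n/5)⌉ bins by default, sorted summation so MI is exactly symmetric);
Welch magnitude-squared coherence (64-sample segments, 50% overlap) and
smoothed Morlet wavelet coherence (ω₀ = 6; Gaussian time smoothing with width
∝ scale, 3-point boxcar across scales), both averaged over 0.01–0.10 Hz
clipped to Nyquist.

The composite edge score z-scores each metric across subjects within each
edge, flips the sign of the four distance metrics so larger always means
stronger coupling, and averages the nine aligned z-scores — producing the one
value per edge that a 20-predictor design requires. A `stacked` mode keeps
the 9-vector and a `pearson_only` mode supports the robustness comparison.
Whether the original analysis aggregated or stacked the nine metrics is not
determinable from the available description; aggregation is the default and
is recorded in the run manifest.

## Learning scores (`learnscores`)

* **SCR.** Per subject and phase, OLS of amplitude on
  (1 + t + t²) × CS; the per-CS score is the sum of successive fitted-value
  differences, which telescopes to ŷ(T) − ŷ(1) (asserted to 1e-10);
  learning = score(CS+) − score(CS−). Trial indices run within CS type
  (a global-index mode exists); reinforced and unreinforced CS+ trials are
  pooled. Scores depend only on fitted values, so raw vs orthogonal
  polynomial coding is immaterial.
* **Behavioural.** A multilevel logistic model (fixed + random intercept and
  trial slope per subject) fit by variational Bayes
  (`statsmodels.BinomialBayesMixedGLM.fit_vb`) with the trial predictor
  standardized internally and back-transformed; Laplace/MAP fitting diverges
  on saturated learning curves, while the VB fit recovers a true fixed slope
  of 0.5 to within ±0.1 at 100 × 80 observations. Complete separation
  (all-0/all-1 subjects) is absorbed by random-effect shrinkage and flagged.
  The learning summary is the expected number of correct responses over the
  8-trial block, Σ p_t ∈ [0, 8]: 4 = binary chance, 8 = perfect. Renewal: a
  renewal response repeats the subject's dominant (majority) acquisition
  response for that stimulus; ties earn no renewal credit.
* **Standardization.** Raw scores are z-scored within study × experiment
  cells (mean 0, population sd 1; idempotent), removing site effects while
  preserving within-cell ordering.
* **Condition test.** Paired CS+/CS− differences, sign-flip permutation on
  the mean, two-sided, add-one convention `(1 + #extreme)/(n_perm + 1)` —
  the convention used by every Monte-Carlo p-value in the package.

## LASSO stability selection (`lassosel`)

Design: z-scored edge predictors (20 or 40) plus penalty-exempt age and sex.
For EC, per-predictor penalty factors proportional to the mean posterior
variance of each coupling (normalized to mean 1) shrink uncertain couplings
harder, mimicking precision weighting; an observation-weight alternative was
considered and rejected as a weaker analogue.

Penalty path: λ_max = max_j |Σ_i x_ij y_i| / n over penalized columns, then
K = 1000 values log-equispaced down to λ_max·ε with ε = 1e-4. One grid per
design (glmnet convention), shared across folds and repetitions.

The solver is cyclic coordinate descent on the Gram matrix (numba-compiled),
objective `(1/2n)‖y − Xβ‖² + λ Σ w_j|β_j|`, warm-started along the path,
converged when the largest coefficient change in a sweep is below 1e-7.
Exempt columns have w_j = 0. Every solution satisfies the KKT conditions to
1e-6, matches soft-thresholding exactly on orthonormal designs, and matches
scikit-learn's Lasso on unweighted problems; scikit-learn cannot express
per-predictor weights or exempt columns, which is why the solver is in-house.

Selection: 100 repetitions × 10 folds; per fold the path is fit on the
training 9/10 (within-fold standardization — prevents leakage) and evaluated
on the held-out fold; the repetition's λ* minimizes mean CV MSE (a 1-SE rule
is optional); each of the 1000 training fits at λ* contributes one selection
vector. Counts are tested with one-sided exact binomial tails against a null
rate p0 and BH-FDR. p0 is not derivable analytically — the null selection
probability at a CV-optimal penalty is data-dependent — so the default policy
estimates it by rerunning the full procedure on outcome-permuted data
(20 runs); a fixed p0 = 0.5 fallback is selectable. Note that at the
minimum-MSE penalty many predictors are nonzero, so raw selection rates are
high for signal and null edges alike; the permutation-calibrated p0 absorbs
the average of this, but the binomial model treats the fits as independent
trials when selections are in fact strongly dependent across folds and edges
(the CV-optimal penalty is shared), so counts are overdispersed and the FDR
flags turn permissive whenever a real effect drags the optimal penalty down.
Selection *ranking* by count is the robust readout; the flags are a
screening, not a familywise guarantee. Measured on matrix-level null
outcomes, the binomial flags fire in ~40% (p0 = 0.5) to ~99% (empirical p0)
of runs at the family level, because a null run whose CV-optimal penalty
happens to land low saturates the whole count vector at once.
`selection_maxcount_test` provides the properly calibrated alternative: it
compares each count against the permutation-null distribution of the
*maximum* count (Westfall–Young single-step; family-wise valid by
construction, ~1% family false flags in the same simulations). Its power is
limited by design: the count statistic is bounded by the number of fits, so
whenever even one permuted run saturates, real effects tie with the null
maximum and cannot reach small p-values — the honest price of calibrated
inference on CV-count statistics. The planted edges still receive the
smallest permutation p-values, consistent with ranking being the reliable
readout; the 1-SE rule mitigates the saturation somewhat.

Companions: ridge / elastic-net / OLS re-fits (scikit-learn backends; the
covariates share the penalty there), Belsley collinearity diagnostics (VIF,
tolerance, eigenvalues, condition indices, variance-decomposition
proportions; exact collinearity reported as an infinite-VIF flag), and the
split-half performance test below.

## Validation battery (`validate`)

* **Split-half MSE test.** One half trains a LASSO (internal CV penalty);
  M Monte-Carlo iterations compare the test-half MSE on true pairings vs
  outcome-shuffled surrogates over a common random subsample; the mean paired
  difference is tested by sign-flipping the M differences. **Size caveat:**
  the sign-flip treats iterations as exchangeable, but all iterations share
  one split, so a split-specific offset inflates the test as M grows relative
  to the test half. Measured null rejection rates at α = .05 (1000 null
  simulations each): 0.042 at n = 800/M = 20; 0.064 at n = 400/M = 20; 0.077
  at n = 200/M = 20 (and ~0.13–0.16 at M = 100). The default M = 20 keeps the
  size near nominal for n ≥ 800 and mildly anticonservative below; results
  near p = .05 at small n should be read accordingly. The same applies to the
  transfer test (0.044–0.054 at n = 400, ~0.08–0.14 at M = 100 on small
  cohorts).
* **Cross-paradigm transfer.** One LASSO trained on a full paradigm; 100
  iterations of 50% subsampling of the other paradigm give paired true and
  surrogate MSEs; sign-flip permutation (10,000 flips) on the mean
  difference.
* **Hub resampling.** 100 Monte-Carlo 80% subsamples; each reruns a reduced
  selection and records the regions (hemispheres collapsed) appearing in
  FDR-significant edges. The internal fits default to the 1-SE rule: at the
  minimum-MSE penalty nearly every edge clears the significance bar under
  subsampling and region counts lose contrast. Counts are modelled with a
  plain Poisson GLM on sum-coded region effects (IRR per region vs the grand
  mean, plus pairwise contrasts, BH-FDR). A mixed Poisson model is not
  identifiable on counts already aggregated per resample, which is why the
  plain GLM replaces it.
* **LOGO.** Fixed predictor set (no re-selection inside folds), OLS refit
  with each study left out; generalisation = Pearson r between pooled
  out-of-fold predictions and observations (per-study-mean variant behind a
  flag). Null behaviour: pooled CV prediction correlations are biased
  slightly *negative* (mean ≈ −0.07 at 4 × 40 subjects), the standard
  cross-validation artifact — positive LOGO correlations are therefore
  conservative. Settings are compared with independent-sample Fisher-z
  tests.
* **Task-window FC.** Per trial, volumes in [onset + 4 s, onset + 8 s] (the
  canonical BOLD peak; configurable) are concatenated per condition; the
  predictor is Pearson FC(CS+) − FC(CS−) per edge; OLS of learning on the
  selected edges + covariates (F, p, R²) against equal-size pseudo-random
  edge sets.
* **MVN simulation.** D datasets of size n drawn from a multivariate normal
  with the reference cohort's mean and covariance of [outcome, predictors,
  covariates]. Each dataset perturbs the moments by their sampling error —
  means and scales by their standard errors and the covariance by a Wishart
  draw at the reference degrees of freedom. The covariance perturbation
  matters: without it the simulated population inherits the reference
  sample's spurious outcome–predictor correlations as exact truths, and the
  paired selected-vs-random R² comparison rejects on null references
  (~25–30% at n_ref = 200, D = 100). Even with it, the simulation can only
  echo the reference sample — a small null reference still yields excess
  rejections; the null calibration is nominal for large references
  (1/20 at n_ref = 1000). Bootstrap variants (rows with/without replacement)
  are provided, and optional pure-noise baseline columns stand in for
  ventricle connectivity.
* **Reliability.** Cronbach's α = k/(k−1)·(1 − Σ item variances / variance
  of the item sum); for session reliability the sessions are the items.

## Problem sizes in the test suites

The acceptance suites run reduced-but-faithful sizes chosen as the package's
own benchmark conditions: bookkeeping at K = 100 on a 100-subject cohort
(1000 fits); type-I calibration with 500 null simulations per test at the
sizes where the sign-flip is exactly calibrated (split-half n = 800/M = 20,
transfer n = 400/M = 10, K = 50); recovery with 3 planted edges at
population R² = 0.15, n = 400, 20 replicates (reps = 20, K = 100,
permutation-calibrated p0); transfer power with a shared R² = 0.2 effect
across an SCR and a behavioural cohort (n = 200 each); MVN comparison with
D = 100 datasets of 40 observations. Power and recovery suites regress the
standardized ground-truth learning scores so the planted R² is exactly the
stated condition; the attenuated trial-measured path has its own tests.

## Known limitations

* The generator's learning curves are linear within the quadratic model
  space; real SCR habituation/curvature, artifacts, and exclusions are not
  emulated, so passing tests certify the statistical machinery, not
  robustness to SCR preprocessing.
* Edge values are mutually independent across edges in the generator (given
  the template); real connectivity has richer dependence, so collinearity
  diagnostics see an easy regime here.
* The split-half/transfer sign-flip tests and the MVN comparison carry the
  size caveats above at paper-scale iteration counts and small references.
* No post-selection inference beyond the binomial/FDR procedure; LASSO
  p-values and confidence intervals remain biased by regularisation, which is
  acknowledged, not solved.
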
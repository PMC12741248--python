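# Methods

This note documents the statistical model behind the package, the
estimators and their numerical choices, what the synthetic cohorts do
and do not emulate, and the design decisions taken where more than one
reasonable option existed.

## The model

Each protein's log2 abundance along age is treated as a smooth random
function observed at a handful of irregular ages per subject,

    Y_ij = X_i(t_ij) + eps_ij,
    X_i(t) = mu(t) + sum_k xi_ik phi_k(t),

a Karhunen–Loève expansion with mean function mu, orthonormal
eigenfunctions phi_k, subject scores xi_ik with Var(xi_ik) = lambda_k
(descending), and iid measurement error eps with variance sigma^2. With
three visits per subject the scores cannot be estimated per subject by
smoothing; the PACE approach (principal analysis by conditional
expectation) pools subjects to estimate mu, the covariance surface
G(s, t) = Cov(X(s), X(t)), sigma^2 and the eigenpairs, and then scores
each subject by the best linear predictor

    xi_hat_ik = lambda_k phi_k(t_i)^T Sigma_i^{-1} (Y_i - mu(t_i)),
    Sigma_i = G(t_i, t_i) + sigma^2 I.

The aging index is built in two steps: per-protein PACE with the first
two components (empirically, FPC1 is close to a level shift — the
cumulative abundance burden — and FPC2 captures age-localized
deviations, i.e. changes of pace), then an elastic-net penalized Cox
regression of all-cause mortality on the concatenated n x 2P score
matrix. The index for subject i is the fitted log hazard ratio

    LPAI_i = sum_j beta_j Z_ij

over the score features with nonzero coefficients, z-scored within a
cohort. New cohorts are scored by projecting their trajectories onto
the frozen training eigenfunctions and applying the stored
coefficients. The index decomposes exactly into FPC1 and FPC2
contributions (sums of the respective weighted scores).

## Normalization convention

Eigenfunctions are orthonormal under the *length-normalized* inner
product (1/L) int f g dt on the training age domain (trapezoid
quadrature). They are therefore O(1) pointwise — "unit mean square over
the domain" — and an eigenvalue is directly the variance that component
contributes to a single observation, so lambda_k / sigma^2 reads as a
per-observation signal-to-noise ratio. This is a units choice only (the
expansion itself is invariant), but all reported eigenvalues, FVE
fractions and scores follow it.

## Smoothing estimators

* **Mean curve**: local-linear kernel regression of the pooled
  (age, value) scatter, evaluated on a 51-point grid spanning the
  training ages. Local-linear fits reproduce affine signals exactly and
  have no boundary bias at first order.
* **Covariance surface**: 2-D local-linear regression of the
  off-diagonal raw covariances (Y_ij - mu)(Y_il - mu), j != l,
  symmetrized. The separable product-kernel structure reduces every
  moment to a (grid x pairs)(pairs x grid) matrix product, so a fit is
  a few ms even with 10^4 pairs; inputs beyond `max_cov_pairs`
  (default 1e5) are subsampled reproducibly.
* **Kernel**: Gaussian by default. With exactly three visits the raw
  covariances live on a few diagonal bands at the observed age lags
  (0/3/18-year offsets give lags 3, 15, 18), and lags beyond the
  largest offset have no pairs at all; a compact-support kernel leaves
  those regions undefined at any usable bandwidth, while the Gaussian
  kernel reaches them through its tails. Epanechnikov remains available
  for dense designs.
* **Bandwidths**: the mean bandwidth defaults to generalized
  cross-validation over a geometric candidate grid. For the covariance
  surface GCV is uninformative — the raw products carry noise orders of
  magnitude larger than the bandwidth-dependent part of the fit, and
  the GCV curve tracks that noise monotonically (we verified the same
  behaviour when scoring against bin means). The default is therefore
  a design-scaled rule: one ninth of the age span, floored at a quarter
  of the largest gap between adjacent observed lags. At that scale the
  local-linear attenuation of domain-scale eigenstructure stays within
  a few percent while each kernel window still averages hundreds of
  pairs at realistic cohort sizes. Pure GCV stays available via
  `bandwidth_cov="gcv"`, and any numeric bandwidth can be given.
* **Noise variance**: a Rice-type paired-difference estimator. For two
  observations of the same subject, E[(r_s - r_l)^2 / 2] = sigma^2 +
  (G(s,s) + G(l,l) - 2 G(s,l))/2; restricting to the shortest observed
  lag and removing the process term via the fitted surface gives an
  estimator whose dominant subject-level variation cancels in the
  difference. Its sampling error is roughly an order of magnitude
  smaller than differencing two separately smoothed curves (the
  classical V(t) - G(t,t) construction, still provided as
  `estimate_noise_variance`). Negative estimates are truncated to zero.
* **Eigendecomposition**: the discretized integral eigenproblem with
  trapezoid weights; eigenvalues truncated at zero, signs fixed so the
  quadrature mean of each eigenfunction is positive (ties: positive
  left endpoint). Internally components are retained to 99% FVE; the
  first two are exposed as index features.
* **Scores**: conditional expectations computed against the PSD
  reconstruction sum_k lambda_k phi_k phi_k^T of the retained
  eigenpairs rather than the raw smoothed surface — the raw surface can
  carry small negative eigenvalues that make within-subject solves
  unstable, and the reconstruction additionally makes scores immune to
  an underestimated sigma^2 (noise orthogonal to the retained
  components never enters). A singular within-subject covariance
  (sigma^2 = 0 with dense ages) falls back to a 1e-8-scaled ridge with
  a warning.

## Penalized Cox step

The solver minimizes -(1/n) Breslow partial log-likelihood plus
lambda [alpha |b|_1 + (1-alpha)/2 |b|_2^2] over a 100-point descending
log-spaced lambda path (down to 1e-3 of the smallest all-zero lambda
when n > p, 1e-2 otherwise). Columns are standardized to unit variance
internally and coefficients returned on the original scale, making the
penalty scale-free; constant columns are excluded with a warning. The
path is solved by scikit-survival's compiled coordinate-descent
(Breslow ties); the unpenalized endpoint (lambda = 0) is fit by
Newton–Raphson with step halving on the same likelihood. The mixing
parameter defaults to alpha = 0.5.

Lambda is chosen by seeded K-fold cross-validation (10 folds; folds
without events are redrawn, at most 5 times). Two criteria are
offered: Verweij–Van Houwelingen partial-likelihood deviance,
-2 (pl_all(b_k) - pl_train(b_k)) per fold, and held-out Harrell's
concordance. The solver defaults to deviance; **index training selects
by concordance**. The reason is empirical and structural: with
hundreds of score features the deviance curve is near-flat over a wide
lambda range and its minimizer admits many pure-noise features, which
measurably dilutes held-out discrimination of the resulting risk score
(the reference R implementation behaves identically on the same
feature matrices, and its 1-SE rule collapses to the null model
there). Cross-validated concordance targets exactly the ranking
performance the index is used for and selects markedly sparser, better
discriminating models. Both criteria remain available via `cv_metric`.

If no feature survives at the selected lambda, training falls back to
the largest path value retaining at least one feature, with a warning.

At the default end-to-end simulation scale (1500 training subjects,
~285 events, 400 score features of which 20 carry signal), held-out
concordance of the trained index typically lands within a few
hundredths of the oracle concordance of the true log hazard, with the
remaining gap set by the number of events relative to the candidate
features rather than by the lambda selection — on unfavorable
replicates the concordance-CV choice already coincides with the best
lambda on the whole path.

## Index construction details

* 70/30 train/test subject splits are uniform without stratification.
* The feature order is frozen in the model (proteins in panel order,
  FPC1 before FPC2) for bit-stable scoring and serialization.
* Standardization: `mode="cohort"` (default) z-scores within the scored
  cohort, matching cohort-specific descriptive reporting;
  `mode="training"` applies the stored training mean/sd for deployment.
  The median dichotomization (low/high) is always cohort-specific.
* In multi-protein fits, "auto" bandwidths are resolved once on the
  first protein and shared across the panel: every protein shares the
  same visit design, which is what determines the bandwidth, and the
  shared value keeps the panel fit linear in the number of proteins.
* Scoring is defined on the trained age domain; subjects observed
  outside it are rejected by name (constant extrapolation of
  eigenfunctions is deliberately not performed).
* Models serialize to JSON (grids, curves, eigenpairs, sigma^2,
  coefficients, standardization) and reload bit-identically.

## Synthetic cohorts

The generator produces the statistical structure the method assumes,
with full ground truth for recovery testing:

* N subjects x P proteins x exactly 3 visits; baseline age uniform on
  [45, 65] by default; visit offsets 0/3/18 years (ARIC-like) or
  0/5/10 (MESA-like).
* Per-protein mean functions drawn from four archetype families —
  flat, logistic rise, logistic decline (both inflecting near age 65)
  and a non-monotone bump — with mild per-protein level and amplitude
  jitter.
* A shared constant + cosine eigenbasis (orthonormal under the
  normalized measure), eigenvalues (2, 0.5) and noise sd 0.5 by
  default, giving a per-observation SNR of 8 on the first component;
  optional nuisance eigenvalues lower the true FVE below 1.
* Survival: exponential with rate h0 exp(eta_i), where eta_i loads
  sparsely on true FPC1 scores of the informative proteins (default 10
  proteins at gamma = 0.155, i.e. sd(eta) ~ 0.69 and a per-SD oracle
  hazard ratio near 2); administrative censoring at 10 years yields
  roughly 20% events; causes assigned by a fixed multinomial
  (cvd/cancer/other = 0.35/0.30/0.35).
* Multimorbidity ~ Poisson(exp(0.7 + 0.3 eta_std)); frailty from a
  proportional-odds model on eta_std with cutpoints (-0.2, 2.2) and
  slope 0.4 (robust/prefrail/frail roughly 45/45/10%).
* Covariates are generated independently of eta by default; a
  `confounding` knob tilts BMI, activity, eGFR and comorbidity
  prevalences along eta for adjusted-vs-unadjusted comparisons.

What the generator does **not** emulate: assay plate/batch noise
structure beyond the additive/multiplicative shifts used in the
ComBat checks, realistic age distributions beyond uniform ranges,
protein–protein correlation (proteins are independent given age),
informative dropout, or competing-risk dependence (causes are
independent of covariates given an event). Passing recovery tests
therefore demonstrates correctness of the estimators under the model's
own assumptions, not robustness to their violation in real cohorts.

Study sizes used by the test suite and the acceptance script — chosen
as the smallest cohorts at which the Monte-Carlo checks are
well-powered: dense limit 200 subjects x 50 points; sparse recovery
1000 subjects x 20 proteins; support recovery n = 2000, p = 400;
end-to-end index 2000 subjects x 200 proteins (1500 train / 500 test,
10 informative); null calibration 20 cohorts of 400 subjects x 30
proteins; clustering 200 proteins.

## Evaluation statistics

Cox hazard ratios (per SD, Efron ties, Wald CIs) come from lifelines;
Poisson rate ratios and proportional-odds models from statsmodels;
Kaplan–Meier curves and the log-rank test from lifelines; the
cross-sectional age clock from scikit-learn's elastic net. The
per-protein mortality screen, landmark fits (delayed entry) and the
Fine–Gray model run on the package's own Breslow Newton solver, which
supports case weights and counting-process intervals with O(n log n)
risk-set sums. The Fine–Gray implementation keeps subjects with
competing events at risk after their event with
censoring-distribution weights G(t)/G(T_i) on an expanded
counting-process dataset; it agrees with `cmprsk::crr` to ~1e-6 on
fixtures and reduces exactly to the cause-specific Cox model when no
competing events exist. Its reported standard errors are model-based
(inverse information), not the weighted sandwich — CIs for data with
many competing events are approximate.

Frailty severity is ordered robust < prefrail < frail, so an odds
ratio above 1 means higher odds of a more severe category; a component
count of zero with incomplete data is missing, not robust. The
multimorbidity index weighs MI, PVD, heart failure, COPD, CKD,
diabetes and dementia once and stroke and cancer twice (theoretical
maximum 11).

The trajectory clustering z-scores each protein's pooled observations,
smooths them with degree-1 tricube LOESS (span 0.75 by default) on a
common grid, and clusters curves by k-means (20 seeded restarts,
labels renumbered by descending cluster size). The elbow rule measures
curvature as the second difference of log WSS: on the log scale a
constant proportional decay — the signature of splitting noise — is a
straight line, so the maximizer marks where the decay rate collapses.
A raw second difference locks onto the earliest large drop whenever
cluster separations are heterogeneous and cannot recover planted
four-cluster structure.

## Batch correction

Parametric empirical-Bayes location/scale correction per protein with
visits as batches and chronological age preserved through the
standardization model. Estimates match Bioconductor `sva::ComBat` to
numerical precision; one deliberate addition is a final per-protein
re-centering to the original grand mean (EB shrinkage otherwise
perturbs it by a small constant). Re-adjusting an already adjusted
matrix is not exactly a no-op: the second pass re-estimates batch
effects from finite data and shrinks a nonzero fraction of that noise,
changing values at the ~0.5% RMS level; exact idempotence would
require dropping the EB shrinkage.

## Known limitations

* Three observations per subject identify at most three score
  dimensions per protein; components beyond the second are supported
  by pooling alone and are not exposed as index features.
* The covariance bandwidth rule is tuned to few-visit designs; dense
  functional data should override it (a small numeric bandwidth or
  `"gcv"`).
* The CV-concordance selection used for index training is slightly
  conservative in feature count; users wanting the glmnet-equivalent
  behaviour can set `cv_metric="deviance"`.
* Scoring does not extrapolate outside the trained age domain.
* Fine–Gray standard errors are model-based (see above).
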
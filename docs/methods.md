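# Methods

This note documents the models implemented in `memloop`, the synthetic-data
generator's assumptions, the numerical choices made where the design was
genuinely open, and the limits of what the test suite demonstrates.

## The generating model

The generator emulates a two-arm closed-loop verbal-memory study. Each
subject-site carries a latent profile drawn once per subject: a random
intercept on recall log-odds (SD `intercept_sd`, default 0.30), a random
stimulation slope (SD `subject_sd`, default 0.15), per-feature baseline
log-power levels and scales, a lognormal multiplier on the spectral memory
effect (`sme_scale_sd`, default 0.25, which spreads classifier performance
across subjects), and a synthetic anatomy (probes of up to 6 contacts
assigned lobe-level region labels; the lateral-temporal arm always carries a
temporal probe, the control arm none).

**Recall.** Each word's recall is Bernoulli with

    logit p = logit(p0) + u_subj
              + (b_stim + v_subj) · stimulated
              + b_flank · flanking

where `p0` is the group profile's baseline (0.261 lateral-temporal, 0.298
non-lateral — the conditional, median-subject rate), `b_stim` the
stimulation log-odds (log 1.18 and log 0.87 in the two shipped profiles) and
`b_flank` the spillover effect on immediate unstimulated neighbors of a
stimulated word (log 1.15 lateral, 0 control). With `intercept_sd` = 0.30
the marginal recall rate exceeds the conditional `p0` by ≈ 0.4 percentage
points (logistic-normal attenuation); this is inside every tolerance used,
so `p0` is interpreted conditionally, matching the mixed model's estimand.

The generator draws each word's uniform variate once and stores it, so a
closed-loop simulation can re-apply stimulation effects after online trigger
decisions are known: outcomes change only through the stimulation and
flanking terms, and a beneficial effect can only flip forgotten → recalled.

**Features.** Per event, features are unit-variance Gaussian around the
subject's baseline column levels; recalled events are shifted by
+`sme_effect` (in SD units) at the two highest analysis frequencies and
−`sme_effect` at the three lowest, reproducing the canonical pattern of
increased high-frequency and decreased low-frequency power for successful
encoding. The default `sme_effect` = 0.09 was calibrated once so that
record-only-trained classifiers reach a mean held-out NoStim AUC of ≈ 0.61
across 25 subject-sites, the generalization level the pipeline is designed
around, and is frozen in the shipped profiles.

**Raw iEEG.** `simulate_raw` produces monopolar traces: integrated-white
(1/f², slope ≈ −1 to −2 over 3–180 Hz after the white sensor-noise floor),
a 60 Hz line component and slow reference drift shared by all contacts
(removed exactly by the bipolar montage), and event-locked bursts — ~110 Hz
during encoding, scaled by exp(±raw_sme/2) for recalled/forgotten words, and
a ~4.5 Hz oscillation scaled oppositely. `raw_sme` defaults to 0.2, at which
the full raw pipeline (filter → montage → wavelets → z-score → classifier)
reaches held-out AUC ≈ 0.7–0.8 on two sessions: a clean but not trivially
separable signal.

**What the generator does not emulate.** Recall dynamics (output order,
inter-response times), word semantics, non-stationary electrode artifacts,
epileptiform activity, line-noise harmonics, and any dependence of the
trigger on true encoding state beyond what the features carry. Passing tests
therefore demonstrate the estimators' correctness under the stated
generating model, not robustness to the artifacts of clinical recordings.

## Signal processing

* Band-stop: 4th-order Butterworth, 57.5–62.5 Hz, applied forward–backward
  (zero phase; effective order doubles). Harmonics of 60 Hz are not
  filtered. Stop band above Nyquist is a configuration error.
* Bipolar montage: one virtual channel per adjacent contact pair on a probe;
  common-mode rejection is exact by construction.
* Wavelets: Morlet, wave number 5, 8 frequencies geometrically spaced with
  endpoints exactly 3 and 180 Hz (ratio 60^(1/7) ≈ 1.795). Epoch
  [0, 1366) ms from word onset, half-open in sample units, 0-based. 1365 ms
  buffers on both sides are taken **from the surrounding recording** and
  discarded after convolution; mirroring the epoch instead would create a
  phase cusp at the junctions whose power dip leaks about one wavelet length
  into the epoch (measured ~25× at the epoch edge for a pure sinusoid), so
  real-data buffers are required to exist. Power is natural-log transformed
  (any base is absorbed by z-scoring) and time-averaged.
* z-scoring is per (virtual channel × frequency) column, population SD
  (ddof = 0). Within-session mode refits on the given events; baseline mode
  applies supplied statistics unchanged. A zero-variance column is an error
  naming the column.

## Classifier

L2-penalized logistic regression in the LIBLINEAR convention
(½‖W‖² + C Σᵢ cᵢ·logloss), C = 2.4 × 10⁻⁴, class weights n/(2 n_k),
intercept unpenalized (scikit-learn `lbfgs`, tol 1e-10 — deterministic given
data). AUC is the Mann–Whitney statistic with ties counting one half. The
permutation test shuffles labels and refits the full pipeline each
iteration; AUC is evaluated by stratified 5-fold cross-validation **inside**
the loop, because in-sample AUC of a refit direction is optimistically
biased above 0.5 regardless of penalty strength (AUC is scale-invariant in
the weights), which would contradict the 0.50 chance level the test is
calibrated against. p = (1 + #{null ≥ observed}) / (n_perm + 1).

The forward model A = Σₓ W / σ²_logit(ŷ) uses biased (1/n) covariance and
variance over the attribution events supplied by the caller — an
interpretation choice; training-set and evaluation-set attributions differ
only through those events. Group maps average subject maps within
region × frequency cells and attach one-sample t statistics.

## Closed loop

Baseline normalization statistics are fit on practice + lists 1–3 and refit
after each completed NoStim list on all non-Stim-list events so far
(stimulated physiology is excluded from normalization as contaminated).
Trigger comparison is strict (< 0.5; exactly 0.5 does not trigger).
Target selection takes the electrode pair with the largest two-sample t
statistic of mean z-power at frequencies ≥ 70 Hz (recalled vs forgotten),
preferring lateral-temporal pairs when present; ties break to the lowest
pair index. Stimulation parameters maximize the pretest change in classifier
output under the amplitude safety cap, ties to lower amplitude then lower
frequency.

The post-stimulation effect on decoded state is parameterized on the
probability scale (`stim_feature_delta`, default 0.01): the next word's
features are shifted along the classifier direction by exactly the amount
that moves its decoded probability by that value (back-solved through the
subject's own weights). Within a full closed-loop session, the measured
Δ-classifier contrast (stim vs matched) is diluted below the per-train shift
because the anchor word wᵢ of a consecutive pair is itself sometimes a
post-stimulation word; the recovery analyses therefore generate the
consecutive-word delta table directly at the configured shift.

## Effect models

The primary model is a binomial logistic mixed model of recalled status on
condition (stimulated vs matched NoStim words), random intercepts and
condition slopes per subject and per site (sites belong to single subjects,
so the crossed specification reduces to nesting; site blocks are included
when sites subdivide subjects). Fitting maximizes the Laplace approximation
of the marginal likelihood (`memloop.glmm`): an inner Newton solve for the
joint penalized mode given variance parameters, and an outer Nelder-Mead
over the ≤ 4 log-SDs. Log-SDs are bounded in [−6, 2]; the lower bound
collapses a component to effectively zero, which reproduces the ordinary
logistic GLM to < 1e-3 on the coefficients. Estimates agree with
`lme4::glmer` to ≈ 0.003 on the condition coefficient at the design scale
(checked in the test suite). Standard errors come from the Schur complement
of the joint Hessian; t statistics use residual degrees of freedom (n − p),
two-tailed α = 0.05 throughout, no multiple-testing correction in the
primary models.

The log-binomial model (GLM, log link) reports the condition coefficient as
a relative risk and as percent change 100·(RR − 1); if the log link diverges
or fits probabilities ≥ 1 it falls back to a modified-Poisson surrogate
(Poisson GLM, HC1 robust errors), flagged in the estimate's notes. The
Δ-classifier model is a linear mixed model (REML, statsmodels `MixedLM`)
with subject intercepts/slopes and site variance components when sites
subdivide subjects. Balance checks use linear mixed models of the
below-threshold indicator by group and position × group, and a two-sample
t-test of per-subject record-only recall percentages.

## Problem sizes and recovery designs

Recovery studies use the study's design scale: ~29 subject-sites × ~130
analyzed words (lateral arm), ~11 sites × ~185 words (control arm), ~1,400
consecutive-word pairs across 18 sites for the Δ-classifier model; three
subjects carry two sites. Acceptance recoveries average 100 seeded
replicates; the test suite uses 30 replicates with bands widened for the
extra Monte-Carlo error. The end-to-end generalization check uses 25
synthetic subject-sites with 3 record-only sessions each at the frozen
default profile.

## Known limitations

* The Laplace approximation is first-order; with very few subjects or
  near-zero variance components its variance estimates (not the fixed
  effects) can sit on the boundary — flagged in the estimate notes rather
  than raised.
* Degrees of freedom are residual (n − p), not Satterthwaite; p-values at
  these sample sizes are indistinguishable, but small-sample inference would
  need a better approximation.
* The pipeline stages operate at the feature level by default; raw-signal
  simulation is exercised through the library API, and serialization of raw
  signals uses an HDF5 container (no EDF writer is available).
* `RandomEffectBlock` variances are independent (no intercept–slope
  correlation), matching the generator; correlated random effects are not
  implemented.
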
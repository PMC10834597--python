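# Methods

## Problem

Observational cohorts record, for each patient, covariates `x`, a binary
treatment `T` (1 = treated, e.g. radical surgery; 0 = conservative
management), a follow-up time in months and an event indicator. Because
treatment is assigned by clinicians, not at random, the two arms differ
systematically (confounding), and arm sizes are typically very imbalanced
(~80/20 here). The package estimates, for each patient, the *individual
treatment effect on survival*: how much longer the patient would survive
under one treatment than under the other, and turns it into a per-patient
treatment recommendation whose population-level value is then audited.

## Model

The estimator is a counterfactual Cox network with a balanced shared
representation:

- a **shared trunk** Φ: a five-layer self-normalizing network (SELU
  activations, alpha-dropout 10%, LeCun-normal initialization) mapping
  standardized covariates to a latent code `z = Φ(x)`;
- two **risk heads** h₀, h₁: identical four-layer self-normalizing networks
  (final layer linear, width 1) mapping `z` to an arm-specific log hazard
  ratio `s_a = h_a(Φ(x))`;
- two **Breslow baseline cumulative hazards** H₀⁽⁰⁾, H₀⁽¹⁾ estimated on the
  training arms after the network is trained.

The training objective is

    L = PL₀ + PL₁ + α · S_ε(Z₀, Z₁)

where PL_a is the mean negative Cox partial log-likelihood (Breslow tie
convention) of head `a` on the subjects who actually received treatment
`a`, and S_ε is the debiased Sinkhorn divergence (entropically smoothed
p-Wasserstein cost, default p = 2, ε = 0.5) between the latent codes of the
two arms in the mini-batch. The balancing term penalizes representations
from which the treatment arm can be told apart — the representation-learning
counterpart of propensity adjustment. With α = 0 the model degenerates to a
T-learner with a shared trunk.

**Latent normalization.** The divergence is computed on latents scaled to
unit mean squared norm. This is essential, not cosmetic: the Cox likelihood
improves by only a fraction of a nat between a null and a well-fitted model,
so with an unnormalized penalty the global optimum is to collapse the latent
cloud to a point (the divergence of two collapsed clouds is zero) — a known
trivial solution of IPM-penalized representations. Scale normalization makes
the penalty invariant to shrinkage, so it can only be reduced by genuinely
aligning the two arm distributions; it also gives the smoothing parameter a
dimension-free meaning (typical squared distances are O(1) for any latent
width).

All gradients — through the SELU layers, the partial likelihood, and the
Sinkhorn divergence (via the envelope theorem: the derivative of the
entropic cost with respect to the cost matrix is the optimal plan) — are
computed in closed form in NumPy and verified against finite differences in
the test suite. Optimization is mini-batch Adam.

**Early stopping.** Training stops when the validation loss has not
strictly improved for `patience` optimizer steps (default 1000) or at
`max_iterations`; the best-validation weights are restored. When no
validation set is supplied, a fraction (default 20%) of the training data,
stratified by arm and event status, is held out. Validation can be
evaluated every `val_every` steps to save time; the patience still counts
optimizer steps.

**Hyperparameters.** Layer counts follow the architecture above; widths
default to 64-64-32-32-16 (trunk) and 32-32-16-1 (heads) and are free
configuration, as are the balance weight α (default 1.0), learning rate
(1e-3), batch size (256) and Sinkhorn ε. `tune` selects over a user grid by
k-fold cross-validation (default 5 folds, stratified by arm × event), mean
best validation loss, ties broken by grid order.

## Counterfactual inference

For a subject `x` and arm `a`, the individual survival curve is
`S_a(t|x) = exp(−H₀⁽ᵃ⁾(t)·exp(s_a(x)))`, a right-continuous step function
supported on the arm's observed event times. The **time at risk** TaR is
the first time the curve reaches 90% mortality (S ≤ 0.1; the threshold is a
parameter). When the curve never reaches it within the baseline's support,
the TaR is capped at the last baseline time and flagged rather than
extrapolated; capped values remain comparable and the flags are surfaced in
every output table. The **ITE** is `TaR¹ − TaR⁰`, and a subject is
recommended for treatment exactly when ITE > 0 (a zero effect defaults to
no treatment).

## Recommendation evaluation

Subjects whose actual treatment equals the recommendation form the
*consistent* group. The survival advantage of consistency is summarized by:

- **HR** — hazard ratio of the consistency indicator from a multivariate
  Cox fit (all covariates as adjusters, Breslow ties; lifelines). With
  weights, a robust sandwich variance supplies the CI.
- **RD** — mortality risk difference at the horizon, in percentage points,
  from (weighted) Kaplan–Meier curves.
- **dRMST** — difference in restricted mean survival time (area under the
  step curves) up to the horizon, in months.
- **log-rank** — (weighted) two-sample log-rank test.
- **IBS** — arm-wise integrated Brier score of the model's predicted
  curves, inverse-probability-of-censoring weighted (censoring distribution
  by Kaplan–Meier), integrated to the horizon and normalized by it.

Default horizon: 120 months (10 years). Each contrast is reported
unadjusted and IPTW-adjusted. The propensity model (logistic regression,
unpenalized) predicts consistency-group membership by default — the
quantity whose imbalance the correction targets — with treatment-assignment
weighting available as an option. Weights are stabilized by marginal group
probabilities and truncated at their 1st/99th percentiles to guard against
positivity violations. CIs for RD/dRMST/IBS are nonparametric bootstrap
percentiles (default 200 resamples of subjects; degenerate resamples are
skipped); the HR CI comes from the Cox variance. With all-unit weights the
adjusted metrics reproduce the unadjusted ones exactly (the robust variance
is engaged only when weights actually vary).

Comparators: a **T-learner Cox** baseline (one unpenalized Cox model per
arm, Breslow baselines, then the identical TaR/ITE/recommendation
machinery) and a declarative **rule recommender** (ordered covariate
predicates, first match wins) for guideline-style policies. A **feature
ablation** utility retrains the network without named column groups (same
seed and configuration) and reports the change in overall and arm-wise IBS.

## Synthetic cohorts

`generate_cohort` draws covariates (five standard normal continuous, two
3-level categoricals, one-hot), assigns treatment by a logistic propensity
(intercept 1.587, solved so that ~80% are treated; coefficients 0.7/−0.5 on
the first two covariates induce confounding with pre-weighting SMDs > 0.3),
and draws event times from a Weibull proportional-hazards model

    S(t|x,T) = exp(−(λt)^k · exp(xβ + T·(xγ + γ₀)))

with λ = 0.02/month, k = 1.2, β = (0.5, −0.3, 0.3, 0.15, 0, …) plus small
categorical effects, γ = (−0.8, 0.5, 0, …) and γ₀ = −0.3 — treatment is
protective on average but harmful for a substantial minority, so the true
ITE sign varies across subjects. Censoring is exponential (0.002/month)
plus an administrative horizon at 240 months; both are independent of
covariates, satisfying the IPCW assumptions of the Brier stage. The truth
table (closed-form TaR under both arms, ITE, propensity) is returned
separately from the dataset so no pipeline stage can consume oracle columns.

Two deliberate departures from registry-like cohorts: (1) the event rate is
high (~85% observed deaths) so that the 90%-mortality time falls inside the
observed support for ~90% of subjects — with a low event rate the TaR is
not identified within follow-up, both counterfactual TaRs are capped at the
same point and the ITE degenerates to zero, making effect-recovery claims
meaningless; (2) hazards are exactly proportional and log-linear, so
recovery results certify the estimation machinery, not robustness to
misspecification. Passing tests therefore show that the pipeline estimates
what it claims under its stated assumptions; they do not show that those
assumptions hold in any particular clinical dataset, nor how the method
degrades under non-PH hazards, informative censoring or unmeasured
confounding.

## Numerical choices

- Cox ties: Breslow everywhere (loss, baselines, lifelines fits agree).
- Step functions: right-continuous; TaR uses the first-crossing rule; RMST
  integrates the step curve exactly (no trapezoids); the Brier integral is
  trapezoidal over the unique event times plus the endpoints, matching the
  scikit-survival convention on a shared grid.
- Sinkhorn: log-domain, damped simultaneous (Jacobi) potential updates —
  exactly symmetric under swapping the two point sets, unlike alternating
  updates — stopped at relative fixed-point residual 1e-9 or 2000
  iterations; debiased with the two self-terms. The training loop relaxes
  the solve to 1e-6/300 iterations: stochastic gradients do not need
  machine-precision transport plans.
- Standardization: non-binary columns only, training-set mean/SD, stored in
  the results object and re-applied at inference.
- Collinearity: full one-hot blocks are reduced to a maximal independent
  column set (QR with pivoting) before logistic/Cox fits; constant columns
  are dropped with a warning.
- Determinism: a single seed fans out (SeedSequence) to weight
  initialization, the validation split, batching, dropout and fold
  assignment; fitting and inference are bit-reproducible given the seed.
- Degenerate inputs fail loudly: empty arms, event-free arms, zero-event
  batches (contribute zero with a logged warning), non-finite losses
  (abort with a learning-rate hint), curves never reaching the TaR
  threshold (capped and flagged).

## Problem sizes

The test suite and the acceptance script run at deliberately modest scale:
reference cohorts of n = 2000–4000 (10,000–20,000 for distributional
checks), 600–2500 optimizer steps, bootstrap 100–200. These sizes were
chosen so the whole pipeline — including three α-sweep retrainings and the
ablation retrainings — completes quickly on a single CPU while leaving the
Monte-Carlo margins of the tested properties intact.

## Known limitations

- No uncertainty on individual ITEs; only group-level contrasts carry CIs.
- Efron tie handling, competing risks and time-varying covariates are not
  implemented; cause-specific survival is handled only by censoring
  non-cause deaths.
- The Sinkhorn penalty is computed per mini-batch; very small minority-arm
  batch counts make it noisy (batches are sampled without stratification).
- Checkpoints store dense weights as JSON: fine at these network sizes,
  wasteful for much larger ones.
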
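# snbsurv

Individual treatment effects on survival from confounded observational
cohorts, with self-normalizing balanced counterfactual networks.

## The problem

When a treatment (say, radical surgery versus conservative management) is
assigned by clinicians rather than at random, comparing survival between
the arms confounds the treatment's effect with the patients' prognosis, and
the *average* effect hides that some patients benefit while others are
harmed. `snbsurv` estimates, per patient, the counterfactual survival curve
under each treatment, summarizes each curve by its **time at risk** (TaR;
the time to reach 90% mortality, i.e. the first `t` with `S(t) ≤ 0.1`), and
defines the **individual treatment effect**

    ITE = TaR(T=1) − TaR(T=0)   (months),

recommending treatment exactly when ITE > 0. It then audits the
recommendation policy: patients whose actual treatment matched the
recommendation (*consistent*) are compared with the rest on hazard ratio,
risk difference, restricted-mean-survival-time difference and log-rank
test, unadjusted and after inverse probability of treatment weighting
(IPTW), plus arm-wise censoring-weighted integrated Brier scores.

## The model

A shared five-layer self-normalizing trunk Φ (SELU activations,
alpha-dropout, LeCun-normal initialization) feeds two four-layer risk heads
h₀, h₁ — one per treatment arm — producing arm-specific log hazard ratios.
Training minimizes

    L = CoxPL₀ + CoxPL₁ + α · S_ε(Φ(X)₀, Φ(X)₁),

the arm-wise Cox partial likelihoods (Breslow ties) plus a debiased
Sinkhorn (entropic 2-Wasserstein) divergence that penalizes latent
representations from which the treatment arm can be told apart — the
representation-learning counterpart of propensity adjustment for
confounded assignment. Arm-specific Breslow baseline hazards turn head
outputs into counterfactual curves `S_a(t|x) = exp(−H₀⁽ᵃ⁾(t) e^{h_a(Φ(x))})`.
Everything (network gradients, Cox gradients, Sinkhorn gradients) is
implemented in NumPy; standard survival fits go through lifelines and the
propensity model through scikit-learn. See `docs/methods.md` for the full
account.

A confounded Weibull proportional-hazards simulator with closed-form true
TaR/ITE per subject ships with the package, so every stage is testable
end-to-end without any data download.

## Worked example

```python
import numpy as np
import snbsurv as sb

# a confounded cohort (~80% treated) with heterogeneous true effects
data, truth = sb.generate_cohort(sb.SimConfig(n_subjects=4000, seed=11))
idx = np.random.default_rng(5).permutation(data.n)
train, test = data.subset(idx[:2800]), data.subset(idx[2800:])

config = sb.SNBConfig(seed=1, balance_weight=1.0, learning_rate=1e-3,
                      max_iterations=2500, patience=600, val_every=10)
results = sb.SNBModel(train, config).fit()
print(results.summary())

rec = results.recommend(test)                      # tar0, tar1, ite, ...
truth_test = truth.iloc[idx[2800:]]
acc = np.mean((rec["ite"] > 0).to_numpy() == (truth_test["ite"] > 0).to_numpy())
print(f"ITE sign accuracy vs simulator truth: {acc:.3f}")

report = sb.evaluate(test, rec, results, horizon=120.0, seed=1)
print(report.summary())
```

This prints:

```
SNB counterfactual survival model
========================================
subjects (train):        2800
  control / treated:     534 / 2266
  events:                2457
features:                11
latent dimension:        16
balance weight:          1.0
iterations run:          920
best iteration:          320
best validation loss:    8.752387
ITE sign accuracy vs simulator truth: 0.853
Recommendation effect (consistent vs inconsistent)
====================================================
n consistent / inconsistent: 698 / 502
horizon: 120 months
HR               0.567  (0.495, 0.649)
HR (IPTW)        0.499  (0.430, 0.580)
RD %            14.218  (9.496, 17.737)
RD % (IPTW)     16.540  (11.408, 21.080)
dRMST mo        18.754  (14.241, 22.109)
dRMST (IPTW)    21.825  (17.111, 25.871)
IBS arm0         0.167  (0.154, 0.178)
IBS arm1         0.169  (0.162, 0.176)
log-rank p            5.24e-18
log-rank p (IPTW)     1.655e-23
```

Read: the network recovers the sign of the true individual effect for 85%
of held-out subjects. Patients whose actual treatment agreed with the
model's recommendation died at ~0.57 times the rate of those whose
treatment disagreed (~0.50 after IPTW), had a 14-point lower 10-year
mortality and gained ~19 months of restricted mean survival — on a cohort
where the simulator guarantees that following the *true* ITE sign is
beneficial. The IBS rows measure calibration of the predicted curves
within each actual arm (0 is perfect, 0.25 is an uninformative constant
1/2).

A command-line interface mirrors the library:

```bash
snb simulate --out cohort.parquet --truth truth.parquet --seed 7
snb fit      --data cohort.parquet --out model.snb
snb predict  --model model.snb --data cohort.parquet --out ite.parquet
snb evaluate --data cohort.parquet --ite ite.parquet --model model.snb --out report.json
```

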
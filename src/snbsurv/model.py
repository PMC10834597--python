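"""The SNB estimator: a self-normalizing, representation-balanced
counterfactual survival network.

Architecture: a shared self-normalizing trunk maps covariates to a latent
representation; two treatment-specific risk heads map the latent code to a
log hazard ratio, one per arm. The training objective is

    L = CoxPL(arm 0) + CoxPL(arm 1) + alpha_ipm * SinkhornDivergence(Z0, Z1)

where the Cox terms are arm-wise negative partial log likelihoods (Breslow
ties) of the head outputs and the last term is the debiased entropic
p-Wasserstein divergence between the latent clouds of the two arms. The
balancing term penalizes arm-separability of the representation, which is
what corrects for confounded treatment assignment; with ``alpha_ipm = 0``
the model degenerates to a T-learner with a shared trunk.

Training is plain mini-batch Adam with early stopping on a validation loss:
the run stops once the validation loss has not improved for ``patience``
optimizer steps (default 1000), and the best-validation weights are
restored. After training, treatment-specific Breslow baseline cumulative
hazards are estimated on the training arms, completing the pieces needed for
counterfactual survival curves.

Usage follows the statsmodels convention::

    model = SNBModel(train_data, SNBConfig(seed=1))
    results = model.fit()
    ite = results.recommend(test_data)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import inference
from .cox import breslow_baseline, cox_partial_loglik, cox_partial_loglik_grad
from .data import SurvivalDataset
from .snn import MLP, Adam, LayerSpec
from .transport import sinkhorn_divergence, sinkhorn_divergence_grad

logger = logging.getLogger(__name__)

# Sinkhorn solver effort inside the training loop: stochastic gradients do
# not need machine-precision transport plans, so convergence is relaxed
# relative to the metric-quality defaults of snbsurv.transport.
_SOLVER_MAX_ITER = 300
_SOLVER_TOL = 1e-6

__all__ = ["SNBConfig", "SNBModel", "SNBResults", "EarlyStopping", "snb_loss", "tune"]


def _default_shared_layers() -> list[LayerSpec]:
    widths = (64, 64, 32, 32, 16)
    return [LayerSpec(w, "selu", 0.10) for w in widths]


def _default_risk_layers() -> list[LayerSpec]:
    return [LayerSpec(32, "selu", 0.10), LayerSpec(32, "selu", 0.10),
            LayerSpec(16, "selu", 0.10), LayerSpec(1, "linear", 0.0)]


@dataclass
class SNBConfig:
    """Hyperparameters of the SNB estimator.

    The five-layer shared trunk (10% alpha-dropout) and the two identical
    four-layer risk heads are the default architecture; layer widths are
    free hyperparameters. ``balance_weight`` is the trade-off multiplier on
    the latent balancing penalty; ``patience`` counts optimizer steps without
    validation improvement before stopping.
    """

    shared_layers: list[LayerSpec] = field(default_factory=_default_shared_layers)
    risk_layers: list[LayerSpec] = field(default_factory=_default_risk_layers)
    balance_weight: float = 1.0
    wasserstein_p: int = 2
    sinkhorn_blur: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_iterations: int = 4000
    patience: int = 1000
    val_fraction: float = 0.2
    val_every: int = 1
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.balance_weight < 0:
            raise ValueError("balance_weight must be >= 0")
        if self.wasserstein_p not in (1, 2):
            raise ValueError("wasserstein_p must be 1 or 2")
        if self.sinkhorn_blur <= 0:
            raise ValueError("sinkhorn_blur must be positive")
        if self.risk_layers[-1].width != 1:
            raise ValueError("final risk layer must have width 1 (the log hazard ratio)")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for key in ("shared_layers", "risk_layers"):
            d[key] = [spec.__dict__.copy() for spec in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SNBConfig":
        d = dict(d)
        for key in ("shared_layers", "risk_layers"):
            if key in d:
                d[key] = [LayerSpec(**s) for s in d[key]]
        return cls(**d)


class EarlyStopping:
    """Stop when the monitored loss has not strictly improved for `patience` steps."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_iteration = 0

    def update(self, iteration: int, loss: float) -> bool:
        """Record the loss at `iteration`; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_iteration = iteration
        return iteration - self.best_iteration >= self.patience


def _standardize_fit(X: np.ndarray):
    """Training-set mean/SD for non-binary columns (binary left untouched)."""
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isin(np.unique(col), (0.0, 1.0)).all():
            continue
        mean[j] = col.mean()
        s = col.std()
        sd[j] = s if s > 0 else 1.0
    return mean, sd


def _arm_cox_with_grad(scores, time, event, arm_label: str):
    """Arm-wise Cox loss and score gradient; event-free arms contribute 0."""
    if scores.size == 0 or event.sum() == 0:
        if scores.size:
            logger.warning("batch has zero events in the %s arm; "
                           "its Cox term contributes 0", arm_label)
        return 0.0, np.zeros_like(scores)
    return cox_partial_loglik_grad(scores, time, event)


def _rms_normalize(Z: np.ndarray):
    """Scale latents to unit mean squared norm per point.

    The balancing divergence is computed on ``Z / r`` with
    ``r = sqrt(mean_i ||Z_i||^2)``: without this, shrinking the
    representation toward a constant minimizes the penalty trivially (the
    divergence of two collapsed clouds is 0) and the trunk collapses, a
    well-known failure mode of IPM-penalized representations. Normalization
    makes the penalty scale-invariant — it can only be reduced by actually
    aligning the arm distributions — and puts typical squared distances on
    an O(1) scale regardless of the latent width, so the smoothing
    parameter has a dimension-free meaning.
    """
    r = float(np.sqrt(np.mean(np.sum(Z ** 2, axis=1)))) + 1e-12
    return Z / r, r


def _rms_normalize_backward(Z: np.ndarray, Zn: np.ndarray, r: float,
                            G: np.ndarray) -> np.ndarray:
    """Gradient of L(Z / r(Z)) given G = dL/dZn."""
    n_points = Z.shape[0]
    return G / r - (np.sum(G * Zn) / (n_points * r)) * Zn


def snb_loss(batch: SurvivalDataset, shared: MLP, risk0: MLP, risk1: MLP,
             config: SNBConfig) -> float:
    """Evaluation-mode value of the joint training objective on a batch.

    Sum of the arm-wise Cox partial-likelihood losses plus
    ``balance_weight`` times the latent Sinkhorn divergence (computed on
    RMS-normalized latents). Single-arm batches skip the balancing term
    with a logged warning.
    """
    Z = shared(batch.X)
    loss = 0.0
    for a, net in ((0, risk0), (1, risk1)):
        mask = batch.treatment == a
        if mask.any() and batch.event[mask].sum() > 0:
            s = net(Z[mask]).ravel()
            loss += cox_partial_loglik(s, batch.time[mask], batch.event[mask])
        elif mask.any():
            logger.warning("batch has zero events in arm %d; Cox term is 0", a)
    m0, m1 = batch.treatment == 0, batch.treatment == 1
    if config.balance_weight > 0:
        if m0.any() and m1.any():
            Zn, _ = _rms_normalize(Z)
            loss += config.balance_weight * sinkhorn_divergence(
                Zn[m0], Zn[m1], p=config.wasserstein_p, eps=config.sinkhorn_blur,
                max_iter=_SOLVER_MAX_ITER, tol=_SOLVER_TOL)
        else:
            logger.warning("single-arm batch: balancing term skipped")
    return float(loss)


class SNBModel:
    """Counterfactual survival model, statsmodels-style.

    Parameters
    ----------
    data : SurvivalDataset
        Training cohort; both arms must contain events.
    config : SNBConfig, optional
    """

    def __init__(self, data: SurvivalDataset, config: SNBConfig | None = None):
        data.require_both_arms_with_events()
        self.data = data
        self.config = config or SNBConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates, treatment, time,
                       event, config: SNBConfig | None = None, **kwargs):
        data = SurvivalDataset.from_dataframe(df, covariates, treatment,
                                              time, event, **kwargs)
        return cls(data, config)

    # --- internals ----------------------------------------------------------

    def _build_networks(self, rngs):
        cfg = self.config
        shared = MLP(self.data.p, cfg.shared_layers, rngs[0])
        risk0 = MLP(shared.out_dim, cfg.risk_layers, rngs[1])
        risk1 = MLP(shared.out_dim, cfg.risk_layers, rngs[2])
        return shared, risk0, risk1

    @staticmethod
    def _zero_grads(net: MLP):
        return [(np.zeros_like(W), np.zeros_like(b))
                for W, b in zip(net.weights, net.biases)]

    def _step_loss_and_grads(self, shared, risk0, risk1, Xb, tb, timeb, eventb,
                             rng):
        """One training-mode forward/backward pass; returns (loss, flat grads)."""
        cfg = self.config
        Z, cache_s = shared.forward(Xb, training=True, rng=rng)
        dZ = np.zeros_like(Z)
        loss = 0.0
        risk_grads = []
        for a, net in ((0, risk0), (1, risk1)):
            mask = tb == a
            if not mask.any():
                risk_grads.append(self._zero_grads(net))
                continue
            s, cache_r = net.forward(Z[mask], training=True, rng=rng)
            li, gi = _arm_cox_with_grad(s.ravel(), timeb[mask], eventb[mask],
                                        "control" if a == 0 else "treated")
            loss += li
            g_params, g_in = net.backward(cache_r, gi[:, None])
            risk_grads.append(g_params)
            dZ[mask] += g_in
        m0, m1 = tb == 0, tb == 1
        if cfg.balance_weight > 0 and m0.any() and m1.any():
            Zn, r = _rms_normalize(Z)
            val, g0, g1 = sinkhorn_divergence_grad(
                Zn[m0], Zn[m1], p=cfg.wasserstein_p, eps=cfg.sinkhorn_blur,
                max_iter=_SOLVER_MAX_ITER, tol=_SOLVER_TOL)
            loss += cfg.balance_weight * val
            G = np.zeros_like(Zn)
            G[m0] = g0
            G[m1] = g1
            dZ += cfg.balance_weight * _rms_normalize_backward(Z, Zn, r, G)
        elif cfg.balance_weight > 0:
            logger.warning("single-arm batch: balancing term skipped")
        shared_grads, _ = shared.backward(cache_s, dZ)
        flat = []
        for pair_list in (shared_grads, *risk_grads):
            for dW, db in pair_list:
                flat.extend([dW, db])
        return loss, flat

    def _validation_loss(self, shared, risk0, risk1, data: SurvivalDataset,
                         Xv: np.ndarray) -> float:
        batch = SurvivalDataset(Xv, data.treatment, data.time, data.event,
                                feature_names=list(data.feature_names))
        return snb_loss(batch, shared, risk0, risk1, self.config)

    def _split_validation(self, rng):
        """Stratified (arm x event) holdout of ``val_fraction`` for early stopping."""
        n = self.data.n
        val_mask = np.zeros(n, dtype=bool)
        strata = self.data.treatment * 2 + self.data.event
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            rng.shuffle(idx)
            k = max(1, int(round(self.config.val_fraction * idx.size)))
            val_mask[idx[:k]] = True
        return self.data.subset(~val_mask), self.data.subset(val_mask)

    # --- fitting ------------------------------------------------------------

    def fit(self, val: SurvivalDataset | None = None,
            verbose: bool = False) -> "SNBResults":
        """Train the network and estimate arm-specific Breslow baselines.

        If ``val`` is omitted, a stratified fraction of the training data is
        held out for early stopping. Deterministic given ``config.seed``.
        """
        cfg = self.config
        ss = np.random.SeedSequence([cfg.seed, 2718281828])
        child = [np.random.default_rng(s) for s in ss.spawn(5)]
        rng_init0, rng_init1, rng_init2, rng_batch, rng_drop = child

        if val is None:
            train, val = self._split_validation(rng_batch)
        else:
            train = self.data
        train.require_both_arms_with_events()
        val.require_both_arms_with_events()

        mean, sd = _standardize_fit(train.X)
        Xt = (train.X - mean) / sd
        Xv = (val.X - mean) / sd

        shared, risk0, risk1 = self._build_networks((rng_init0, rng_init1, rng_init2))
        params = shared.parameters() + risk0.parameters() + risk1.parameters()
        opt = Adam(params, lr=cfg.learning_rate)
        stopper = EarlyStopping(cfg.patience)
        best_state = None
        log: list[dict] = []

        n = train.n
        perm = rng_batch.permutation(n)
        cursor = 0
        last_val = np.inf
        for it in range(1, cfg.max_iterations + 1):
            if cursor + cfg.batch_size > n:
                perm = rng_batch.permutation(n)
                cursor = 0
            idx = perm[cursor:cursor + cfg.batch_size]
            cursor += cfg.batch_size
            loss, grads = self._step_loss_and_grads(
                shared, risk0, risk1, Xt[idx], train.treatment[idx],
                train.time[idx], train.event[idx], rng_drop)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at iteration {it}; "
                    "try a smaller learning_rate")
            opt.step(grads)

            if it % cfg.val_every == 0:
                last_val = self._validation_loss(shared, risk0, risk1, val, Xv)
                if last_val < stopper.best:
                    best_state = (shared.get_state(), risk0.get_state(),
                                  risk1.get_state())
                should_stop = stopper.update(it, last_val)
            else:
                should_stop = False
            log.append({"iteration": it, "train_loss": float(loss),
                        "val_loss": float(last_val)})
            if verbose and it % 100 == 0:
                logger.info("iter %d train %.4f val %.4f", it, loss, last_val)
            if should_stop:
                break

        if best_state is not None:
            shared.set_state(best_state[0])
            risk0.set_state(best_state[1])
            risk1.set_state(best_state[2])

        baselines = {}
        for a, net in ((0, risk0), (1, risk1)):
            mask = train.treatment == a
            s = net(shared(Xt[mask])).ravel()
            times, cumhaz = breslow_baseline(s, train.time[mask], train.event[mask])
            baselines[a] = (times, cumhaz)

        return SNBResults(
            model=self, shared=shared, risk0=risk0, risk1=risk1,
            baselines=baselines, scaler=(mean, sd), config=cfg,
            training_log=pd.DataFrame(log),
            best_iteration=stopper.best_iteration,
            best_val_loss=float(stopper.best),
            n_iterations=log[-1]["iteration"] if log else 0,
        )


def tune(data: SurvivalDataset, grid: list[dict],
         config: SNBConfig | None = None) -> SNBConfig:
    """K-fold cross-validated hyperparameter selection.

    ``grid`` is a list of config-field override dicts. For each grid point
    the mean best validation loss over ``cv_folds`` folds (stratified by arm
    and event status, deterministic given the seed) is computed; the argmin
    is returned, ties broken by grid order.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    base = config or SNBConfig()
    rng = np.random.default_rng(np.random.SeedSequence([base.seed, 31415926]))
    folds = np.zeros(data.n, dtype=int)
    strata = data.treatment * 2 + data.event
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % base.cv_folds
    best_score, best_cfg = np.inf, None
    for point in grid:
        cfg = replace(base, **point)
        scores = []
        for f in range(base.cv_folds):
            train = data.subset(folds != f)
            val = data.subset(folds == f)
            res = SNBModel(train, cfg).fit(val=val)
            scores.append(res.best_val_loss)
        score = float(np.mean(scores))
        if score < best_score:
            best_score, best_cfg = score, cfg
    return best_cfg


class SNBResults:
    """Fitted SNB: network weights, arm-specific baselines, standardization.

    Provides counterfactual survival curves, per-patient time-at-risk and
    individual treatment effects, and treatment recommendations; see the
    ``predict_survival`` / ``individual_treatment_effect`` / ``recommend``
    methods and :mod:`snbsurv.inference`.
    """

    def __init__(self, model, shared, risk0, risk1, baselines, scaler, config,
                 training_log, best_iteration, best_val_loss, n_iterations):
        for a in (0, 1):
            times, cumhaz = baselines[a]
            if np.any(np.diff(cumhaz) < -1e-12) or (cumhaz.size and cumhaz[0] < 0):
                raise ValueError(f"baseline hazard for arm {a} is not nondecreasing")
        self.model = model
        self.shared = shared
        self.risk = {0: risk0, 1: risk1}
        self.baselines = baselines
        self.scaler = scaler
        self.config = config
        self.training_log = training_log
        self.best_iteration = best_iteration
        self.best_val_loss = best_val_loss
        self.n_iterations = n_iterations

    # --- prediction surface -------------------------------------------------

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the training-set standardization."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean, sd = self.scaler
        if X.shape[1] != mean.size:
            raise ValueError(
                f"input has {X.shape[1]} columns, model was trained on {mean.size} "
                f"({self.model.data.feature_names})")
        return (X - mean) / sd

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Latent representation (shared trunk output, evaluation mode)."""
        return self.shared(self.transform(X))

    def predict_score(self, X: np.ndarray, arm: int) -> np.ndarray:
        """Predicted log hazard ratio under counterfactual treatment ``arm``."""
        if arm not in (0, 1):
            raise ValueError("arm must be 0 or 1")
        return self.risk[arm](self.latent(X)).ravel()

    def predict_survival(self, X, arm: int):
        return inference.predict_survival(self, X, arm)

    def individual_treatment_effect(self, x, mortality_threshold: float = 0.90):
        return inference.individual_treatment_effect(
            self, x, mortality_threshold=mortality_threshold)

    def recommend(self, data, mortality_threshold: float = 0.90) -> pd.DataFrame:
        return inference.recommend_batch(
            self, data, mortality_threshold=mortality_threshold)

    def swap_arms(self) -> "SNBResults":
        """Results with treatment labels relabelled (risk heads and baselines
        exchanged); every ITE is exactly negated."""
        return SNBResults(
            model=self.model, shared=self.shared,
            risk0=self.risk[1], risk1=self.risk[0],
            baselines={0: self.baselines[1], 1: self.baselines[0]},
            scaler=self.scaler, config=self.config,
            training_log=self.training_log,
            best_iteration=self.best_iteration,
            best_val_loss=self.best_val_loss, n_iterations=self.n_iterations)

    # --- reporting ----------------------------------------------------------

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "SNB counterfactual survival model",
            "=" * 40,
            f"subjects (train):        {d.n}",
            f"  control / treated:     {(d.treatment == 0).sum()} / {(d.treatment == 1).sum()}",
            f"  events:                {d.event.sum()}",
            f"features:                {d.p}",
            f"latent dimension:        {self.shared.out_dim}",
            f"balance weight:          {self.config.balance_weight}",
            f"iterations run:          {self.n_iterations}",
            f"best iteration:          {self.best_iteration}",
            f"best validation loss:    {self.best_val_loss:.6f}",
        ]
        return "\n".join(lines)

    # --- persistence --------------------------------------------------------

    _SCHEMA = 1

    def save(self, path: str) -> None:
        """Write a single-file JSON checkpoint (weights, baselines, scaler,
        resolved config)."""
        def net_state(net):
            return {"specs": [s.__dict__.copy() for s in net.specs],
                    "in_dim": net.in_dim,
                    "weights": [W.tolist() for W in net.weights],
                    "biases": [b.tolist() for b in net.biases]}
        payload = {
            "schema": self._SCHEMA,
            "config": self.config.to_dict(),
            "feature_names": list(self.model.data.feature_names),
            "scaler_mean": self.scaler[0].tolist(),
            "scaler_sd": self.scaler[1].tolist(),
            "shared": net_state(self.shared),
            "risk0": net_state(self.risk[0]),
            "risk1": net_state(self.risk[1]),
            "baselines": {str(a): {"times": t.tolist(), "cumhaz": h.tolist()}
                          for a, (t, h) in self.baselines.items()},
            "best_iteration": int(self.best_iteration),
            "best_val_loss": float(self.best_val_loss),
            "n_iterations": int(self.n_iterations),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "SNBResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != cls._SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {payload.get('schema')}")

        def build_net(state):
            net = MLP.__new__(MLP)
            net.in_dim = state["in_dim"]
            net.specs = [LayerSpec(**s) for s in state["specs"]]
            net.weights = [np.asarray(W, dtype=float) for W in state["weights"]]
            net.biases = [np.asarray(b, dtype=float) for b in state["biases"]]
            return net

        cfg = SNBConfig.from_dict(payload["config"])
        shared = build_net(payload["shared"])
        risk0 = build_net(payload["risk0"])
        risk1 = build_net(payload["risk1"])
        baselines = {int(a): (np.asarray(v["times"], dtype=float),
                              np.asarray(v["cumhaz"], dtype=float))
                     for a, v in payload["baselines"].items()}

        class _LoadedModel:
            """Minimal stand-in carrying the training schema of a checkpoint."""
            def __init__(self, names):
                self.data = type("MetaData", (), {
                    "feature_names": names, "n": None, "p": len(names),
                    "treatment": np.array([]), "event": np.array([])})()

        res = cls(model=_LoadedModel(payload["feature_names"]),
                  shared=shared, risk0=risk0, risk1=risk1,
                  baselines=baselines,
                  scaler=(np.asarray(payload["scaler_mean"], dtype=float),
                          np.asarray(payload["scaler_sd"], dtype=float)),
                  config=cfg, training_log=None,
                  best_iteration=payload["best_iteration"],
                  best_val_loss=payload["best_val_loss"],
                  n_iterations=payload["n_iterations"])
        return res
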
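"""Shared fixtures: simulated cohorts and a trained reference model.

The expensive fixtures are session-scoped so the trained network is fitted
once and reused by the parameter-recovery, inference and acceptance tests.
"""

import numpy as np
import pytest

import snbsurv as sb


@pytest.fixture(scope="session")
def het_cohort():
    """Reference confounded cohort (n=4000, heterogeneous effect) with a
    70/30 train/test split and the matching truth tables."""
    cfg = sb.SimConfig(n_subjects=4000, seed=11)
    data, truth = sb.generate_cohort(cfg)
    idx = np.random.default_rng(5).permutation(data.n)
    tr, te = idx[:2800], idx[2800:]
    return {
        "config": cfg,
        "train": data.subset(tr),
        "test": data.subset(te),
        "truth_train": truth.iloc[tr].reset_index(drop=True),
        "truth_test": truth.iloc[te].reset_index(drop=True),
    }


@pytest.fixture(scope="session")
def fit_config():
    """Training configuration used for the fitted reference model."""
    return sb.SNBConfig(seed=1, balance_weight=1.0, learning_rate=1e-3,
                        max_iterations=2500, patience=600, val_every=10,
                        batch_size=256)


@pytest.fixture(scope="session")
def snb_results(het_cohort, fit_config):
    """SNB fitted on the reference training cohort (reused across tests)."""
    return sb.SNBModel(het_cohort["train"], fit_config).fit()


@pytest.fixture(scope="session")
def tiny_fit():
    """A small, quickly trained model for mechanics/determinism tests."""
    cfg = sb.SimConfig(n_subjects=500, seed=7)
    data, _ = sb.generate_cohort(cfg)
    mcfg = sb.SNBConfig(seed=3, balance_weight=0.5, max_iterations=80,
                        patience=80, val_every=20, batch_size=128,
                        learning_rate=2e-3)
    return data, mcfg, sb.SNBModel(data, mcfg).fit()
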
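"""Shared fixtures: small deterministic scenarios and the multi-seed recovery study."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import ssemlasso as sl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario():
    """A quick 10-gene scenario with a fixed penalty, for plumbing tests."""
    config = sl.SimulationConfig(p=10, n_train=80, seed=11, n_tests=1)
    net, train, tests = sl.generate_scenario(config)
    fit = sl.fit_network(train, sl.LassoConfig(penalty_mode="fixed", fixed_lambda=0.05))
    return config, net, train, tests, fit


@pytest.fixture(scope="session")
def recovery_study():
    """Parameter-recovery study at the reference conditions, over 20 seeds.

    Reference conditions: 20 genes, 500 training samples, spectral radius
    0.5, noise sd 0.25, one single-target test experiment with shift
    5 x noise sd and 2 replicates; per-row 5-fold CV Lasso.  Returns one
    record per seed with the averaged SSEM and z-score rank of the true
    target, the directed-support F1 of B-hat against B-true, and sign
    agreement counts on strong true coefficients (|B_true| >= 0.3).
    """
    records = []
    for seed in range(20):
        config = sl.SimulationConfig(seed=seed)
        net, train, tests = sl.generate_scenario(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sl.fit_network(train, sl.LassoConfig(seed=seed))
        spec, experiment = tests[0]
        target = spec.targets[0]
        ssem = [
            sl.rank_genes(sl.compute_residuals(fit, experiment.column(c)))
            for c in experiment.samples
        ]
        zsc = [sl.zscore_ranking(train, experiment.column(c)) for c in experiment.samples]
        ssem_rank = float(sl.average_rankings(ssem).loc[target, "mean_rank"])
        z_rank = float(sl.average_rankings(zsc).loc[target, "mean_rank"])
        true_support = net.B_true != 0
        est_support = fit.B_hat != 0
        tp = int((true_support & est_support).sum())
        fp = int((~true_support & est_support).sum())
        fn = int((true_support & ~est_support).sum())
        f1 = 2 * tp / max(2 * tp + fp + fn, 1)
        strong = true_support & (np.abs(net.B_true) >= 0.3)
        sign_ok = int((np.sign(fit.B_hat[strong]) == np.sign(net.B_true[strong])).sum())
        records.append(
            {
                "seed": seed,
                "p": config.p,
                "target": target,
                "ssem_rank": ssem_rank,
                "z_rank": z_rank,
                "f1": f1,
                "strong": int(strong.sum()),
                "sign_ok": sign_ok,
                "net": net,
                "fit": fit,
            }
        )
    return records
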
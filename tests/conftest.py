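import numpy as np
import pytest

import recurpred as rp
from recurpred.io import ROLE_TRAIN


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate-signal cohort, small enough for fast unit tests."""
    cfg = rp.SimConfig(n_genes=300, n_samples=80, n_batches=5, seed=7)
    expr, samples, truth = rp.generate_cohort(cfg)
    return cfg, expr, samples, truth


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with a loud planted signature (1.5 SD shift, 10% DE genes)."""
    cfg = rp.SimConfig(
        n_genes=400, n_samples=120, frac_de_genes=0.1, effect_size_delta=1.5,
        gene_sd_range=(1.0, 1.0), n_batches=4, seed=11,
    )
    expr, samples, truth = rp.generate_cohort(cfg)
    return cfg, expr, samples, truth


def training_table(samples):
    return samples[(samples["role"] == ROLE_TRAIN) & (~samples["is_reference"])]


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """Small trained ensemble with out-of-bag scores."""
    _, expr, samples, truth = small_cohort
    tr = training_table(samples)
    plan = rp.make_splits(len(tr), 3, 80, seed=5)
    model = rp.train_ensemble(expr, samples, plan, m=40)
    scores = rp.score_internal(model)
    return model, scores, tr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
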
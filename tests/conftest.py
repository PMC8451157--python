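"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from methylrestore.synth import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_study():
    """Default-condition study at 2000 probes (effects, DMRs, eQTM, outcomes)."""
    config = SimulationConfig(seed=11, n_probes=2000)
    meth, expr, outcomes, truth = generate_dataset(config)
    return {"config": config, "meth": meth, "expr": expr,
            "outcomes": outcomes, "truth": truth}


@pytest.fixture(scope="session")
def null_study():
    """Global-null study: no effects of any kind, single cell component."""
    config = SimulationConfig(
        seed=13, n_probes=2000, k_true=1, n_smoking_cpgs=0,
        n_dmr_clusters=0, n_eqtm_pairs=0, n_outcome_cpgs=0,
    )
    meth, expr, outcomes, truth = generate_dataset(config)
    return {"config": config, "meth": meth, "expr": expr,
            "outcomes": outcomes, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_beta(n_probes=50, n_samples=8, seed=0):
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        r.uniform(0.05, 0.95, size=(n_probes, n_samples)),
        index=[f"cg{i:08d}" for i in range(n_probes)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
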
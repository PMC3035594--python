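import numpy as np
import pandas as pd
import pytest

from ildnet import (ExpressionMatrix, SimulationConfig, simulate_cohort,
                    simulate_knowledge)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort, shared read-only across tests."""
    cfg = SimulationConfig(seed=7)
    mrna, mirna, meta, truth = simulate_cohort(cfg)
    kb = simulate_knowledge(truth, cfg)
    return {"config": cfg, "mrna": mrna, "mirna": mirna, "meta": meta,
            "truth": truth, "kb": kb}


@pytest.fixture()
def small_matrix():
    """Tiny deterministic matrix: 4 features x 4 samples."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.5],
         [0.5, 1.5, 2.5, 3.5]],
        index=["f1", "f2", "f3", "f4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)


def make_matrix(rng, n_features, n_samples, prefix="F"):
    values = rng.standard_normal((n_features, n_samples))
    return ExpressionMatrix(pd.DataFrame(
        values,
        index=[f"{prefix}{i:03d}" for i in range(n_features)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    ))
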
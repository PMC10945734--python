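import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ribote

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_annotation():
    return ribote.simulate_annotation(30, uorf_fraction=0.5, seed=101)


@pytest.fixture(scope="session")
def design():
    return ribote.factorial_design()


@pytest.fixture(scope="session")
def noiseless_counts(small_annotation, design):
    """Deterministic counts (dispersion 0) with a planted interaction of +1
    on the first five genes and true RRO 0.2 everywhere."""
    genes = pd.Index(small_annotation.transcript_ids)
    inter = pd.Series(0.0, index=genes)
    inter.iloc[:5] = 1.0
    truth = ribote.SimulationTruth.build(
        small_annotation,
        base_mean_rna=500.0,
        dispersion=0.0,
        log2_te_interaction=inter,
        true_rro=0.2,
    )
    return ribote.simulate_counts(small_annotation, design, truth, seed=102), truth
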
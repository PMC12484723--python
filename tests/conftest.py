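import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def benchmark_truth():
    """Small proteome with kinase-inhibitor-like target kinetics."""
    from kinact import ProteomeTruth

    return ProteomeTruth.random(n_analytes=60, n_targets=6, seed=11)


@pytest.fixture
def titration_design():
    from kinact.synthetic import spebrutinib_like_design

    return spebrutinib_like_design()
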
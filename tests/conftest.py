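import numpy as np
import pytest
from dataclasses import replace

from spherekin import builtin_scenarios, generate_release_curve


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def noiseless_curves(scenarios):
    """One noise-free replicate per built-in scenario (forward-model truth)."""
    out = {}
    for name, sc in scenarios.items():
        out[name] = generate_release_curve(replace(sc, noise_sd=0.0, n_replicates=1))[0]
    return out
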
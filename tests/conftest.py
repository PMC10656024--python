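import numpy as np
import pytest

from placigg.parameters import default_parameters, default_ranges
from placigg.placenta import simulate


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def ranges():
    return default_ranges()


@pytest.fixture(scope="session")
def baseline_sim(params):
    """One default-parameter term simulation shared across tests."""
    return simulate(params)


@pytest.fixture(scope="session")
def small_design_outcomes(ranges, params):
    """A 150-row LHS design with forward-model outcomes, shared across the
    sensitivity tests to keep the suite fast."""
    from placigg.placenta import subclass_entropy
    from placigg.sensitivity import lhs_design

    design = lhs_design(ranges, 150, seed=42)
    total = np.empty(150)
    entropy = np.empty(150)
    for i, row in enumerate(design.X):
        p = params.with_free_values(dict(zip(design.names, row)))
        res = simulate(p)
        total[i] = res.total_fetal()[-1]
        entropy[i] = subclass_entropy(res.fetal_at_end())
    return design, total, entropy
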
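import numpy as np
import pytest

import lcdr


@pytest.fixture(scope="session")
def scenario_fit():
    """One converged mixture fit on a well-separated scenario, shared by
    tests that only need *a* valid fit (EM diagnostics, quantile curves)."""
    scen = lcdr.Scenario(c=20, alpha1=0.7, n=500, seed=3)
    data = lcdr.simulate_dataset(scen)
    spec = lcdr.scenario_model_spec()
    fit = lcdr.fit_lcdr(data, lcdr.MixtureSpec(components=(spec, spec)))
    assert fit.status == "converged"
    return scen, data, fit


@pytest.fixture(scope="session")
def grid201():
    return np.linspace(0.0, 1.0, 201)
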
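import numpy as np
import pytest
from hypothesis import settings

import dielcycle as dc

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def instrument():
    return dc.InstrumentModel(gain=200.0, cv=0.03)


@pytest.fixture(scope="session")
def degenerate_sim():
    """Perfectly synchronized batch population: sigma = jitter = arrest = 0."""
    params = dc.SimParams(
        n0=2000, sigma_sync=0.0, jitter_s=0.0, jitter_g2=0.0,
        frac_arrested=0.0, seed=1,
    )
    return dc.simulate_population(params, n_days=2)


@pytest.fixture(scope="session")
def hl_sim():
    """Default HL scenario at reduced size, with truth and event samples."""
    from dataclasses import replace

    scen = dc.default_scenarios()["HL"]
    scen = dc.Scenario(scen.name, scen.schedule, replace(scen.params, n0=3000))
    result, samples = dc.simulate_scenario(scen, n_days=1, n_events=20_000, seed=5)
    return result, samples


def make_ct_table(entries):
    """Long-format CT table from (gene, condition, time_h, replicate, ct) tuples."""
    import pandas as pd

    return pd.DataFrame(
        entries, columns=["gene", "condition", "time_h", "replicate", "ct"]
    )
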
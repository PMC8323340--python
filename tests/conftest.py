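import numpy as np
import pandas as pd
import pytest

import ivimva as iv
from ivimva.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_protocol():
    return iv.make_default_protocol()


@pytest.fixture(scope="session")
def noiseless_va_cohort():
    """Noiseless default cohort forward-simulated with the VA model."""
    spec = CohortSpec(snr=None, seed=11)
    table, truth = simulate_cohort(spec, model="va")
    return table, truth


@pytest.fixture(scope="session")
def noiseless_va_fit(noiseless_va_cohort):
    """Pipeline results on the noiseless VA cohort, merged with ground truth."""
    table, truth = noiseless_va_cohort
    res = iv.MultiDiffusionTimeModel(table).fit()
    merged = res.frame.merge(
        truth[["subject", "region", "f", "D", "v", "l", "T0", "Dstar"]],
        on=["subject", "region"], suffixes=("", "_true"))
    return res, merged


def single_region_table(state, protocol, model="va", region="roi", subject="s1",
                        session=1):
    """Noiseless signal table for one region (helper used across test modules)."""
    from ivimva.signal_models import total_signal
    rows = [(subject, session, region, p.b, p.Delta, p.delta, p.direction,
             float(total_signal(p, state, model)) * state.S0)
            for p in protocol]
    df = pd.DataFrame(rows, columns=["subject", "session", "region", "b",
                                     "Delta", "delta", "direction", "signal"])
    return iv.SignalTable(df)
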
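import numpy as np
import pandas as pd
import pytest

from simrecall.scaling import build_similarity_function
from simrecall.tcc import mean_signal, report_pmf


@pytest.fixture(scope="session")
def color_omega():
    """A representative similarity function (color-like parameters)."""
    return build_similarity_function(1.5, 0.103)


def simulate_tcc_trials(resp, d_by_setsize, n_per_setsize, rng,
                        motor_sd_deg=2.0):
    """WM-style trial table sampled from a max-rule report distribution."""
    rows = []
    for n_items, d in d_by_setsize.items():
        pmf = report_pmf(mean_signal(resp, d), motor_sd_deg)
        rows.append(pd.DataFrame({"set_size": n_items,
                                  "error": pmf.sample(n_per_setsize, rng)}))
    return pd.concat(rows, ignore_index=True)


def simulate_nr_trials(gamma, kappa, n_per_setsize, rng, set_sizes=(3, 6)):
    """WM-style trial table sampled from the Poisson population model."""
    from simrecall.synthetic import _sample_nr_errors

    rows = []
    for n_items in set_sizes:
        e = _sample_nr_errors(gamma, kappa, n_items, n_per_setsize, rng)
        rows.append(pd.DataFrame({"set_size": n_items, "error": e}))
    return pd.concat(rows, ignore_index=True)
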
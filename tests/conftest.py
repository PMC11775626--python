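import numpy as np
import pandas as pd
import pytest
from scipy.special import expit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_history(rng, n_sites, n_occasions, psi_coefs, p_logit,
                     covariate=None):
    """Direct small-scale occupancy data generator used as a test oracle
    (independent of the synthetic module)."""
    x = rng.normal(size=n_sites) if covariate is None else covariate
    eta = psi_coefs[0] + (psi_coefs[1] * x if len(psi_coefs) > 1 else 0.0)
    psi = expit(eta)
    z = rng.random(n_sites) < psi
    p = expit(p_logit)
    y = (rng.random((n_sites, n_occasions)) < (z[:, None] * p)).astype(int)
    return y, x, psi, z


@pytest.fixture
def toy_records():
    """Five detection events (plus burst structure) across 3 sites / 4 days."""
    rows = []

    def burst(site, sp, ts, counts, bid):
        t = pd.Timestamp(ts)
        for k, c in enumerate(counts):
            rows.append({"site_id": site, "species": sp,
                         "datetime": t + pd.Timedelta(seconds=k),
                         "count": c, "burst_id": bid})

    burst("A", "tiger", "2023-01-01 06:10:00", (1, 1, 1), "b1")
    burst("A", "tiger", "2023-01-03 22:00:00", (1, 1, 1), "b2")
    burst("B", "tiger", "2023-01-02 04:30:00", (1, 1, 1), "b3")
    burst("B", "chital", "2023-01-02 10:00:00", (2, 2, 1), "b4")
    burst("C", "tiger", "2023-01-04 19:45:00", (1, 1, 1), "b5")
    return pd.DataFrame(rows)


@pytest.fixture
def toy_effort():
    return pd.DataFrame({
        "site_id": ["A", "B", "C"],
        "start": pd.Timestamp("2023-01-01"),
        "end": pd.Timestamp("2023-01-04"),
    })
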
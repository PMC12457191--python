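"""Shared fixtures: small simulated datasets and the replicate battery.

The battery runs the full estimator over a grid of generative settings at
the study scale (m = 150,000, 25 replicates per setting) and is shared by
the calibration tests; everything else uses small, fast fixtures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from sffdr import SfFDR, SimConfig, simulate_independent, storey_qvalue

BATTERY_SETTINGS = {
    "high_large": dict(informative_strength="high", effect_strength="large"),
    "low_large": dict(informative_strength="low", effect_strength="large"),
    "uninformative": dict(informative_strength="high", effect_strength="none"),
    "medium_moderate": dict(informative_strength="medium", effect_strength="moderate"),
}
N_REPLICATES = 25


@pytest.fixture(scope="session")
def small_sim():
    """One modest replicate (m = 20,000) for structural checks."""
    return simulate_independent(
        SimConfig(m=20_000, seed=11, informative_strength="high", effect_strength="large")
    )


def run_battery_setting(name: str, n_replicates: int = N_REPLICATES) -> pd.DataFrame:
    """Simulate -> fit -> evaluate for one generative setting."""
    rows = []
    seeds = np.random.SeedSequence(20_000 + hash(name) % 1000).generate_state(
        n_replicates
    ) % (2**31)
    for rep, seed in enumerate(seeds):
        config = SimConfig(seed=int(seed), **BATTERY_SETTINGS[name])
        ds = simulate_independent(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SfFDR(random_state=int(seed)).fit(ds.z, ds.p)
            storey = storey_qvalue(ds.p)
        sig = model.qvalues_ <= 0.01
        R = int(sig.sum())
        V = int(np.sum(sig & (ds.H == 0)))
        rows.append(
            {
                "replicate": rep,
                "qf_count": R,
                "fdp": V / max(R, 1),
                "storey_count": int(np.sum(storey.qvalues_ <= 0.01)),
                "type1": float(np.mean(model.pvalues_[ds.H == 0] <= 1e-4)),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def battery():
    """Replicate battery over the representative setting grid."""
    return {name: run_battery_setting(name) for name in BATTERY_SETTINGS}
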
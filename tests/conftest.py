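import warnings

import numpy as np
import pandas as pd
import pytest

import recurprof as rp
from recurprof.estimation import ConvergenceWarning


def make_table(rows, covariates=("z",)):
    """Build a validated table from (subject, facility, start, stop, event, *z)."""
    cols = ["subject_id", "facility_id", "start", "stop", "event", *covariates]
    return rp.validate_table(pd.DataFrame(rows, columns=cols))


def random_table(seed, n_fac=3, n_subj=30, tau=60, p=2, rate=0.05):
    """Small random event-history table with staggered entry and gaps."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        fac = int(rng.integers(n_fac))
        z = rng.normal(0, 0.5, p)
        b = int(rng.integers(0, tau - 2))
        x = int(rng.integers(b + 1, tau + 1))
        day, prev = b, b
        while True:
            gap = int(np.ceil(rng.exponential(1.0 / rate)))
            day += gap
            if day > x:
                break
            rows.append((i, fac, prev, day, 1, *z))
            prev = day
        if prev < x:
            rows.append((i, fac, prev, x, 0, *z))
    names = tuple(f"z{k}" for k in range(1, p + 1))
    df = pd.DataFrame(
        rows, columns=["subject_id", "facility_id", "start", "stop", "event", *names]
    )
    if df["event"].sum() == 0:  # pragma: no cover - rate keeps this rare
        df.loc[df.index[0], "event"] = 1
    return rp.validate_table(df)


@pytest.fixture(scope="session")
def small_sim():
    """One small generated population (5 facilities) with its fitted model."""
    cfg = rp.SimulationConfig(
        scenario=1, n_facilities=5, mean_size=30.0, reps=1, seed=5
    )
    rng = np.random.default_rng(np.random.SeedSequence(42))
    table, truth = rp.gen_population(cfg, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fitted = rp.fit_model(table)
    return table, truth, fitted


@pytest.fixture(scope="session")
def scenario3_study():
    """Scenario 3 (independent gap times) Monte-Carlo study, desk scale."""
    cfg = rp.scenario_presets(3)
    cfg.reps = 150
    cfg.seed = 11
    return rp.run_study(cfg)


@pytest.fixture(scope="session")
def scenario4_study():
    """Scenario 4 (gamma-frailty) Monte-Carlo study, desk scale."""
    cfg = rp.scenario_presets(4)
    cfg.reps = 150
    cfg.seed = 11
    return rp.run_study(cfg)
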
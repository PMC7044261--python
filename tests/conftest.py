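"""Shared fixtures.

The expensive artifacts (noiseless self-fit datasets, the 20-experiment
parameter-recovery ensemble) are session-scoped so the module tests and
the acceptance tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from binsum.fitting import (
    FitSpec,
    dipper_predictions,
    eeg_predictions,
    evaluate_fixed,
    fit_dipper,
    fit_eeg,
)
from binsum.observer import DipperDataset, simulate_experiment
from binsum.params import TABLE1
from binsum.ssaep import EEGResponseDataset


@pytest.fixture(scope="session")
def p6a():
    return TABLE1["6a"]


@pytest.fixture(scope="session")
def p6d():
    return TABLE1["6d"]


@pytest.fixture(scope="session")
def noiseless_dipper_data(p6a):
    """Exact model thresholds from the weak-suppression truth, as a dataset."""
    preds = dipper_predictions(p6a, "gain")
    df = pd.DataFrame(
        [
            {"condition": c, "pedestal_pct": P, "threshold_db": v, "n_trials": 0}
            for (c, P), v in preds.items()
        ]
    )
    return DipperDataset(df, n_participants=0)


@pytest.fixture(scope="session")
def noiseless_eeg_data(p6d):
    """Exact model SNRs from the EEG-fit truth, as a dataset."""
    preds = eeg_predictions(p6d, "gain")
    df = pd.DataFrame(
        [
            {"condition": c, "depth_pct": d, "freq_hz": f, "snr": v,
             "n_participants": 0}
            for (c, d, f), v in preds.items()
        ]
    )
    return EEGResponseDataset(df, n_participants=0)


@pytest.fixture(scope="session")
def dipper_selffit(noiseless_dipper_data):
    return fit_dipper(noiseless_dipper_data, FitSpec(n_restarts=20, seed=1))


@pytest.fixture(scope="session")
def eeg_selffit(noiseless_eeg_data):
    return fit_eeg(
        noiseless_eeg_data, FitSpec(n_restarts=20, seed=2, with_sigma35=True)
    )


@pytest.fixture(scope="session")
def recovery_runs(p6a):
    """Twenty seeded observer experiments from the weak-suppression truth,
    each refit freely and with suppression forced to omega = 1.

    Returns a list of dicts with the simulated dataset, the free fit and
    the omega = 1 evaluation.  Study-sized design (6 listeners x 3 reps);
    restart counts are reduced for runtime (the noiseless self-fit
    fixtures cover optimizer thoroughness).
    """
    runs = []
    for i in range(20):
        ds = simulate_experiment(
            p6a, n_participants=6, n_reps=3, rng_seed=1000 + i
        )
        free = fit_dipper(ds, FitSpec(n_restarts=5, seed=i))
        forced = evaluate_fixed(free.params, {"omega": 1.0}, ds)
        runs.append({"data": ds, "free": free, "forced": forced})
    return runs
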
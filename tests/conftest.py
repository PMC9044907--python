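"""Shared fixtures: moderately sized synthetic cohorts, fitted once per session."""

import numpy as np
import pytest

import prescore as ps


@pytest.fixture(scope="session")
def bg_config():
    return ps.default_background_config(seed=42, n_background=8000)


@pytest.fixture(scope="session")
def background(bg_config):
    return ps.generate_background_cohort(bg_config)


@pytest.fixture(scope="session")
def kidney_fit(background, bg_config):
    return ps.fit_cox(background, bg_config.markers, "kidney")


@pytest.fixture(scope="session")
def cv_fit(background, bg_config):
    return ps.fit_cox(background, bg_config.markers, "cv")


@pytest.fixture(scope="session")
def trial_config():
    return ps.default_trial_config(seed=43, n_per_arm=1500)


@pytest.fixture(scope="session")
def trial(trial_config):
    """Complete (no missingness injected) default two-arm trial."""
    return ps.generate_trial(trial_config)


@pytest.fixture()
def tiny_fit():
    """Hand-specified single-marker exponential risk model: beta = 1,
    center = 0, H0(t) = 0.1 * (t / 3.5) up to 3.5 years."""
    knots = np.linspace(1e-9, 3.5, 8)
    return ps.CoxFit(
        outcome="kidney", markers=["x"], transforms=["identity"],
        beta=np.array([1.0]), se=np.array([0.1]),
        covariate_center=np.array([0.0]),
        baseline_times=knots, baseline_cumhaz=0.1 * knots / 3.5,
        n_events=10, n_patients=20,
    )


def make_trial(markers, rows):
    """Small literal trial table; ``rows`` maps column -> list."""
    import pandas as pd

    df = pd.DataFrame(rows)
    if "id" not in df:
        df.insert(0, "id", np.arange(len(df)))
    for o in ps.OUTCOMES:
        if f"time_{o}" not in df:
            df[f"time_{o}"] = 1.0
        if f"event_{o}" not in df:
            df[f"event_{o}"] = 0
    return ps.TrialDataset(df, markers)
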
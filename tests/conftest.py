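import numpy as np
import pandas as pd
import pytest

from imuperf import FEATURE_COLUMNS, default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One seeded 84-participant cohort from the packaged three-group recipe."""
    return generate_cohort(default_cohort_spec(), seed=42)


def _fill(df, frailty_counts, faller_counts):
    """Assign frailty and faller labels with exact per-blob counts."""
    frailty, faller = [], []
    for (n_rob, n_pre, n_fra), (f_rob, f_pre, f_fra) in zip(frailty_counts, faller_counts):
        frailty += ["robust"] * n_rob + ["pre-frail"] * n_pre + ["frail"] * n_fra
        faller += (
            ["yes"] * f_rob + ["no"] * (n_rob - f_rob)
            + ["yes"] * f_pre + ["no"] * (n_pre - f_pre)
            + ["yes"] * f_fra + ["no"] * (n_fra - f_fra)
        )
    df["frailty"] = frailty
    df["faller"] = faller
    return df


@pytest.fixture(scope="session")
def published_margin_cohort() -> pd.DataFrame:
    """Synthetic cohort whose label margins equal the published contingency data.

    Features form three tight separable blobs sized 22/39/23 (low to high
    six-minute-walk distance) so clustering recovers them exactly; frailty and
    faller labels are laid out so that the faller-by-frailty margin is 6/19/9
    of 24/45/15 and the per-performance margins are frail 9/4/2, robust
    4/10/10, pre-frail 9/25/11, fallers 10/16/8.
    """
    rng = np.random.default_rng(7)
    means = {
        "LPP": [8.0, 11.9, 325.0, 0.52, 0.55, 10.5, 9.5],
        "IPP": [11.8, 12.5, 430.0, 0.47, 0.68, 8.8, 6.9],
        "HPP": [12.4, 14.3, 515.0, 0.46, 0.78, 7.9, 5.7],
    }
    sizes = {"LPP": 22, "IPP": 39, "HPP": 23}
    rows = []
    for lab, m in means.items():
        X = np.asarray(m) + rng.normal(0, 0.01, size=(sizes[lab], 7)) * np.asarray(m)
        for x in X:
            rows.append(dict(zip(FEATURE_COLUMNS, x)))
    df = pd.DataFrame(rows)
    df.insert(0, "participant_id", [f"P{i:03d}" for i in range(len(df))])
    df.insert(1, "group_truth", ["LPP"] * 22 + ["IPP"] * 39 + ["HPP"] * 23)
    # per-blob (robust, pre-frail, frail) counts and faller counts within each
    frailty_counts = [(4, 9, 9), (10, 25, 4), (10, 11, 2)]  # cols sum 24/45/15
    faller_counts = [(0, 1, 9), (0, 16, 0), (6, 2, 0)]  # frailty margins 6/19/9
    df = _fill(df, frailty_counts, faller_counts)
    df["sex"] = "F"
    df["age"] = 74.0
    df["height_cm"] = 165.0
    df["body_mass_kg"] = 68.0
    return df
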
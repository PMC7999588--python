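import numpy as np
import pandas as pd
import pytest

import fallwatch as fw


def subject_seed(base: int, i: int) -> int:
    return int(np.random.SeedSequence([base, i]).generate_state(1)[0])


@pytest.fixture(scope="session")
def short_config():
    """Separable-mode cohort with a 10-minute day (fast, same structure)."""
    return fw.CohortConfig(day_duration=600.0)


@pytest.fixture(scope="session")
def cohort(short_config):
    return fw.make_cohort(short_config, seed=1)


@pytest.fixture(scope="session")
def subject_day(short_config, cohort):
    """One simulated low-risk day: (trajectory, ground truth)."""
    return fw.simulate_day(cohort[0], short_config, seed=42)


@pytest.fixture(scope="session")
def cohort_days(short_config, cohort):
    """All 30 simulated days: list of (profile, trajectory, truth)."""
    out = []
    for i, p in enumerate(cohort):
        traj, truth = fw.simulate_day(p, short_config, subject_seed(1, i))
        out.append((p, traj, truth))
    return out


@pytest.fixture(scope="session")
def cohort_features(cohort_days):
    rows = {p.subject_id: fw.extract_parameters(traj).as_dict()
            for p, traj, _ in cohort_days}
    df = pd.DataFrame.from_dict(rows, orient="index")[fw.PARAMETER_NAMES]
    df.index.name = "subject_id"
    return df


@pytest.fixture(scope="session")
def cohort_labels(cohort):
    return fw.label_cohort(cohort)["label"]


@pytest.fixture(scope="session")
def small_camera():
    return fw.CameraModel(width=96, height=72, focal_px=80.0)
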
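"""Shared fixtures and builders for the test suite.

Trajectory fixtures are generated programmatically; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from iplboost import MotionModelParams, TrajectorySet, default_params, simulate_cohort
from iplboost.trajectories import COLUMNS


def make_trajectory_set(vectors, patient_id="P01", fraction_id="F01", dt=5.0) -> TrajectorySet:
    """Build a single-fraction trajectory from explicit (lat, long, vert)
    displacement vectors, sampled every ``dt`` seconds."""
    arr = np.asarray(vectors, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "fraction_id": fraction_id,
            "t_seconds": np.arange(len(arr)) * dt,
            "lat_mm": arr[:, 0],
            "long_mm": arr[:, 1],
            "vert_mm": arr[:, 2],
        }
    )
    return TrajectorySet(df[COLUMNS])


def concat_trajectory_sets(*sets: TrajectorySet) -> TrajectorySet:
    return TrajectorySet(pd.concat([s.data for s in sets], ignore_index=True))


def constant_displacement_set(d_values, axis=0) -> TrajectorySet:
    """One sample per requested radial distance, along a single axis."""
    vecs = np.zeros((len(d_values), 3))
    vecs[:, axis] = d_values
    return make_trajectory_set(vecs)


@pytest.fixture(scope="session")
def small_cohort() -> TrajectorySet:
    """A 10-patient, 3-fraction synthetic cohort at calibrated defaults
    (scaled down in size, not in motion scales)."""
    params = default_params(n_patients=10, fractions_per_patient=3, seed=20260927)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort() -> TrajectorySet:
    """The full default cohort (28 patients × 26 fractions)."""
    return simulate_cohort(default_params())


@pytest.fixture()
def zero_motion_params() -> MotionModelParams:
    return default_params(
        sigma_lat=0.0, sigma_long=0.0, sigma_vert=0.0,
        drift_lat=0.0, drift_long=0.0, drift_vert=0.0,
        patient_motility_sd=0.0, n_patients=2, fractions_per_patient=2,
    )
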
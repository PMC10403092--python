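"""Shared fixtures: small synthetic cohorts and trajectory bundles.

All fixtures are generated programmatically at session scope; nothing is
read from disk.
"""

import numpy as np
import pandas as pd
import pytest

from ventwarn.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_trajectory_bundles,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-encounter cohort with default (planted-signal) settings."""
    cfg = GeneratorConfig(n_encounters=400, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def bundles3():
    """Three well-separated 73-point trajectory bundles (n = 600)."""
    return generate_trajectory_bundles(200, archetypes=3, noise_sd=0.02, seed=1)


@pytest.fixture()
def toy_encounter_frame():
    """Hand-built encounters covering each exclusion rule exactly once."""

    def mk(i, **kw):
        row = dict(
            encounter_id=f"t{i:03d}",
            age_years=5.0,
            gender="Male",
            race="White",
            ethnicity="Hispanic",
            height_cm=110.0,
            weight_kg=20.0,
            admit_time=0,
            discharge_time=5 * 1440,
            mv_flag=False,
            mv_onset_time=np.nan,
            mv_end_time=np.nan,
            niv_flag=False,
            trach_flag=False,
            cyanotic_flag=False,
            manual_exclusion_flag=False,
            diagnosis_categories="respiratory",
            procedure_times="",
        )
        row.update(kw)
        return row

    rows = [
        mk(0),  # clean control
        mk(1, age_years=25.0),  # age out of range
        mk(2, weight_kg=np.nan),  # missing demographics
        mk(3),  # no vitals (no observations emitted below)
        mk(4, manual_exclusion_flag=True),
        mk(5, trach_flag=True),
        mk(6, cyanotic_flag=True),  # low-SpO2 observations below
        mk(7, mv_flag=True, mv_onset_time=10 * 60.0, mv_end_time=40 * 60.0),  # <12 h
        mk(8, mv_flag=True, mv_onset_time=20 * 60.0, mv_end_time=28 * 60.0),  # short MV
        mk(9, mv_flag=True, mv_onset_time=20 * 60.0, mv_end_time=40 * 60.0,
           procedure_times=str(int(20 * 60 - 60))),  # post-procedure onset
        mk(10, mv_flag=True, mv_onset_time=20 * 60.0, mv_end_time=40 * 60.0,
           diagnosis_categories="other"),  # no required dx
        mk(11, mv_flag=True, mv_onset_time=20 * 60.0, mv_end_time=40 * 60.0),  # clean MV
    ]
    enc = pd.DataFrame(rows)

    obs_rows = []
    for r in rows:
        if r["encounter_id"] == "t003":
            continue  # planted: no vitals
        val = 85.0 if r["encounter_id"] == "t006" else 98.0
        for t in range(0, int(r["discharge_time"]), 60):
            obs_rows.append((r["encounter_id"], t, "spo2", val))
        obs_rows.append((r["encounter_id"], 5, "heart_rate", 110.0))
    obs = pd.DataFrame(obs_rows, columns=["encounter_id", "time", "variable", "value"])
    return enc, obs
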
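"""Cohort construction: inclusion/exclusion filtering, MV-prep labeling, split.

The inclusion/exclusion flowchart mirrors standard PICU early-warning study
designs: pediatric age range, complete demographics, at least one vital sign,
no tracheostomy, no cyanotic heart disease with chronically low SpO2, and —
for MV cases — onset at least 12 h after admission, duration at least 12 h,
onset not attributable to a procedure, and a qualifying discharge diagnosis.
Each removed encounter is logged once with the first rule that fired, in
flowchart order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PREP_WINDOW_MINUTES = 30

REQUIRED_ENCOUNTER_COLUMNS = (
    "encounter_id",
    "age_years",
    "gender",
    "weight_kg",
    "admit_time",
    "discharge_time",
    "mv_flag",
    "mv_onset_time",
    "mv_end_time",
    "trach_flag",
    "cyanotic_flag",
    "diagnosis_categories",
    "procedure_times",
)


@dataclass
class CohortFilterConfig:
    min_age_years: float = 0.0
    max_age_years: float = 21.0
    mv_min_hours_after_admit: float = 12.0
    mv_min_duration_hours: float = 12.0
    procedure_window_minutes: float = 90.0
    spo2_baseline_threshold: float = 90.0
    spo2_fraction_of_stay: float = 0.75
    required_diagnosis_categories: frozenset = field(
        default_factory=lambda: frozenset({"respiratory", "cardiovascular", "sepsis"})
    )
    prep_window_minutes: float = PREP_WINDOW_MINUTES

    def __post_init__(self) -> None:
        for name in (
            "mv_min_hours_after_admit",
            "mv_min_duration_hours",
            "procedure_window_minutes",
            "prep_window_minutes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.spo2_baseline_threshold <= 100:
            raise ValueError("spo2_baseline_threshold must lie in (0, 100]")
        if not 0 < self.spo2_fraction_of_stay <= 1:
            raise ValueError("spo2_fraction_of_stay must lie in (0, 1]")


#: (rule_id, human-readable reason) in flowchart order
RULES = (
    ("age_out_of_range", "age outside the pediatric range"),
    ("missing_demographics", "missing age, gender, weight, or LOS"),
    ("no_vital_sign", "no recorded vital sign during the stay"),
    ("manual_exclusion", "transcription error / insufficient ventilation information"),
    ("tracheostomy", "tracheostomy present"),
    ("cyanotic_low_spo2", "cyanotic heart disease with chronically low baseline SpO2"),
    ("mv_within_12h", "MV began within 12 hours of PICU admission"),
    ("mv_duration_lt_12h", "MV duration was less than 12 hours"),
    ("mv_post_procedure", "MV onset within 90 minutes after a documented procedure"),
    ("mv_no_required_dx", "MV case without respiratory/cardiovascular/sepsis diagnosis"),
)

VITAL_VARIABLES = ("heart_rate", "resp_rate", "spo2", "sbp", "dbp", "temp")


def _parse_pipe_list(value) -> list:
    if isinstance(value, (list, tuple, set)):
        return [str(v) for v in value]
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return []
    return str(value).split("|")


def _low_spo2_fraction(times, values, discharge, threshold, grid_step=5):
    """Grid-time-weighted fraction of the stay with SpO2 below threshold.

    Evaluated on the 5-minute last-observation-carried-forward grid; grid
    points before the first observation do not count as low.
    """
    if len(times) == 0:
        return 0.0
    order = np.argsort(times, kind="mergesort")
    times = np.asarray(times, float)[order]
    values = np.asarray(values, float)[order]
    grid = np.arange(0, discharge + 1, grid_step, dtype=float)
    pos = np.searchsorted(times, grid, side="right") - 1
    low = np.zeros(grid.size, bool)
    seen = pos >= 0
    low[seen] = values[pos[seen]] < threshold
    return float(low.mean())


def apply_inclusion_exclusion(
    encounters: pd.DataFrame,
    observations: pd.DataFrame,
    config: CohortFilterConfig | None = None,
):
    """Apply the study flowchart; return (retained encounters, exclusion log).

    The exclusion log has columns ``encounter_id, rule_id, reason``; every
    removed encounter appears exactly once, tagged with the first rule that
    fired.
    """
    config = config or CohortFilterConfig()
    for col in REQUIRED_ENCOUNTER_COLUMNS:
        if col not in encounters.columns:
            raise KeyError(f"encounters table is missing required column {col!r}")
    for col in ("encounter_id", "time", "variable", "value"):
        if col not in observations.columns:
            raise KeyError(f"observations table is missing required column {col!r}")

    enc = encounters.reset_index(drop=True)
    n = len(enc)
    excluded_rule = np.full(n, "", dtype=object)

    los = enc["discharge_time"].to_numpy(float) - enc["admit_time"].to_numpy(float)
    age = enc["age_years"].to_numpy(float)
    mv = enc["mv_flag"].to_numpy(bool)
    onset = enc["mv_onset_time"].to_numpy(float)
    mv_end = enc["mv_end_time"].to_numpy(float)
    admit = enc["admit_time"].to_numpy(float)

    vital_obs = observations[observations["variable"].isin(VITAL_VARIABLES)]
    has_vital = enc["encounter_id"].isin(set(vital_obs["encounter_id"])).to_numpy()

    spo2_obs = observations[observations["variable"] == "spo2"]
    spo2_by_enc = {k: v for k, v in spo2_obs.groupby("encounter_id")}

    manual = (
        enc["manual_exclusion_flag"].to_numpy(bool)
        if "manual_exclusion_flag" in enc.columns
        else np.zeros(n, bool)
    )

    def fire(rule_id: str, mask: np.ndarray) -> None:
        new = mask & (excluded_rule == "")
        excluded_rule[new] = rule_id

    for rule_id, _reason in RULES:
        if rule_id == "age_out_of_range":
            bad = ~np.isnan(age) & (
                (age < config.min_age_years) | (age > config.max_age_years)
            )
        elif rule_id == "missing_demographics":
            bad = (
                np.isnan(age)
                | enc["gender"].isna().to_numpy()
                | enc["weight_kg"].isna().to_numpy()
                | np.isnan(los)
            )
        elif rule_id == "no_vital_sign":
            bad = ~has_vital
        elif rule_id == "manual_exclusion":
            bad = manual
        elif rule_id == "tracheostomy":
            bad = enc["trach_flag"].to_numpy(bool)
        elif rule_id == "cyanotic_low_spo2":
            bad = np.zeros(n, bool)
            cyan = enc["cyanotic_flag"].to_numpy(bool)
            for i in np.flatnonzero(cyan & (excluded_rule == "")):
                obs_i = spo2_by_enc.get(enc.at[i, "encounter_id"])
                if obs_i is None:
                    continue
                frac = _low_spo2_fraction(
                    obs_i["time"].to_numpy(float),
                    obs_i["value"].to_numpy(float),
                    los[i],
                    config.spo2_baseline_threshold,
                )
                bad[i] = frac >= config.spo2_fraction_of_stay
        elif rule_id == "mv_within_12h":
            bad = mv & (onset - admit < config.mv_min_hours_after_admit * 60.0)
        elif rule_id == "mv_duration_lt_12h":
            bad = mv & (mv_end - onset < config.mv_min_duration_hours * 60.0)
        elif rule_id == "mv_post_procedure":
            bad = np.zeros(n, bool)
            for i in np.flatnonzero(mv & (excluded_rule == "")):
                for p in _parse_pipe_list(enc.at[i, "procedure_times"]):
                    p = float(p)
                    if 0 <= onset[i] - p <= config.procedure_window_minutes:
                        bad[i] = True
                        break
        elif rule_id == "mv_no_required_dx":
            bad = np.zeros(n, bool)
            req = set(config.required_diagnosis_categories)
            for i in np.flatnonzero(mv):
                cats = set(_parse_pipe_list(enc.at[i, "diagnosis_categories"]))
                bad[i] = not (cats & req)
        else:  # pragma: no cover
            raise AssertionError(rule_id)
        fire(rule_id, bad)

    reasons = dict(RULES)
    dropped = excluded_rule != ""
    log = pd.DataFrame(
        {
            "encounter_id": enc.loc[dropped, "encounter_id"].to_numpy(),
            "rule_id": excluded_rule[dropped],
            "reason": [reasons[r] for r in excluded_rule[dropped]],
        }
    )
    retained = enc.loc[~dropped].reset_index(drop=True)
    return retained, log


def label_mv_prep(encounter, prep_window_minutes: float = PREP_WINDOW_MINUTES) -> float:
    """Return the MV-preparation time: onset minus the prep window (minutes).

    All grid samples in the half-open interval [prep_time, mv_onset) must be
    dropped from training and testing — intubation drugs given there would
    leak the outcome.
    """
    if isinstance(encounter, pd.Series):
        mv_flag = bool(encounter["mv_flag"])
        onset = float(encounter["mv_onset_time"])
    else:
        mv_flag = bool(encounter.mv_flag)
        onset = float(encounter.mv_onset_time)
    if not mv_flag:
        raise ValueError("label_mv_prep requires an MV encounter")
    return onset - prep_window_minutes


AGE_GROUP_BINS = (1.0, 5.0, 12.0)  # <1, 1-4, 5-11, 12-21 years


def age_group(age_years) -> np.ndarray:
    return np.digitize(np.asarray(age_years, float), AGE_GROUP_BINS)


def stratified_split(
    encounters: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
):
    """Split encounter ids into (train, test), stratified by MV outcome,
    gender, age group, and NIV status.

    Within every stratum the train share is ``round(train_fraction * n)``;
    singleton strata go to train with a logged warning.  Deterministic for a
    given seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    df = encounters.reset_index(drop=True)
    strata = (
        df["mv_flag"].astype(bool).astype(str)
        + "|" + df["gender"].astype(str)
        + "|" + age_group(df["age_years"]).astype(str)
        + "|" + df["niv_flag"].astype(bool).astype(str)
    )
    train_ids, test_ids = [], []
    for _, grp in df.groupby(strata, sort=True):
        ids = grp["encounter_id"].to_numpy()
        if ids.size == 1:
            logger.warning("stratum of size 1 assigned to train: %s", ids[0])
            train_ids.extend(ids)
            continue
        perm = rng.permutation(ids.size)
        n_train = int(round(train_fraction * ids.size))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return sorted(train_ids), sorted(test_ids)
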
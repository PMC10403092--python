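"""Synthetic PICU cohort generator.

Emulates the statistical structure of a single-center PICU EHR cohort so the
downstream pipeline (cohort filtering, feature grids, medication-sentence
learning, risk modeling, trajectory clustering) is fully testable without any
clinical data.  The generator reproduces the marginal structure the pipeline
assumes — MV prevalence ~8.6% (1176/13651), age and length-of-stay contrasts
between the MV and no-MV groups (median LOS 19.4 vs 3.1 days, median age 1.2
vs 4.8 years), NIV prevalence 28.4% vs 10.7% — plus two planted predictive
signals in MV encounters:

* physiologic drift (rising respiratory/heart rate, falling SpO2, rising
  PEWS, escalating IV-fluid volumes) ramping up over a configurable lead
  window before MV onset, scaled by ``signal_strength`` and a per-encounter
  severity level; and
* outcome-dependent medication sequences: in the pre-onset window, a
  first-order chain over (medication, action) tokens shifts mass toward a
  configurable set of predictive medications and toward escalation patterns
  ("given" followed by repeated "rate changed").

No attempt is made at clinically realistic pharmacology or physiology; only
the statistical structure the pipeline consumes.  Timestamps are integer
minutes since admission.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MINUTES_PER_DAY = 1440.0
ACTIONS = ("given", "rate changed", "stopped")

#: fraction of encounters planted to violate each cohort rule, so the
#: inclusion/exclusion flowchart is exercised end to end.
RULE_VIOLATION_RATES = {
    "missing_weight": 0.010,
    "missing_gender": 0.004,
    "no_vitals": 0.005,
    "trach": 0.008,
    "cyanotic_low_spo2": 0.006,
    "manual_exclusion": 0.003,
    # conditional on mv_flag:
    "mv_early_onset": 0.04,
    "mv_short_duration": 0.03,
    "mv_post_procedure": 0.02,
    "mv_no_required_dx": 0.02,
}

RACES = ("White", "Black", "Asian", "Pacific Islander", "Other")
RACE_P = (0.473, 0.063, 0.052, 0.014, 0.398)
ETHNICITIES = ("Hispanic", "Non-Hispanic", "Other")
ETHNICITY_P = (0.480, 0.517, 0.003)
DIAGNOSES = ("respiratory", "cardiovascular", "sepsis", "neurologic", "trauma", "other")


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate_cohort`.

    ``los_lognormal_params`` holds per-outcome-group ``(mu, sigma)`` of the
    log length of stay in minutes; defaults place the LOS medians at 19.4
    days (MV) and 3.1 days (no-MV).  ``signal_strength`` is a log-odds-scale
    dial on all planted effects; 0 yields a cohort with no outcome signal.
    """

    n_encounters: int = 2000
    mv_prevalence: float = 1176 / 13651
    seed: int = 0
    med_vocab_size: int = 60
    n_predictive_meds: int = 8
    signal_strength: float = 3.0
    obs_rate_per_hour: float = 1.0
    los_lognormal_params: dict = field(
        default_factory=lambda: {
            "mv": (math.log(19.4 * MINUTES_PER_DAY), 0.55),
            "no_mv": (math.log(3.1 * MINUTES_PER_DAY), 0.80),
        }
    )
    trajectory_archetypes: int = 3
    niv_prevalence_by_group: tuple = (0.284, 0.107)  # (MV, no-MV)
    drift_lead_hours: float = 12.0
    med_event_rate_per_hour: float = 0.30
    decoy_control_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        if not 0.0 < self.mv_prevalence < 1.0:
            raise ValueError("mv_prevalence must lie in (0, 1)")
        if self.med_vocab_size < 1:
            raise ValueError("med_vocab_size must be >= 1")
        if not 0 <= self.n_predictive_meds <= self.med_vocab_size:
            raise ValueError("n_predictive_meds must lie in [0, med_vocab_size]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if self.obs_rate_per_hour <= 0:
            raise ValueError("obs_rate_per_hour must be positive")
        if self.trajectory_archetypes < 1:
            raise ValueError("trajectory_archetypes must be >= 1")
        for frac in self.niv_prevalence_by_group:
            if not 0.0 < frac < 1.0:
                raise ValueError("niv_prevalence_by_group fractions must lie in (0, 1)")
        if self.med_event_rate_per_hour <= 0:
            raise ValueError("med_event_rate_per_hour must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "los_lognormal_params" in raw:
            raw["los_lognormal_params"] = {
                k: tuple(v) for k, v in raw["los_lognormal_params"].items()
            }
        if "niv_prevalence_by_group" in raw:
            raw["niv_prevalence_by_group"] = tuple(raw["niv_prevalence_by_group"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# baseline physiology used both here and by the default normal-range table
# ---------------------------------------------------------------------------

def vital_baseline(variable: str, age_years: np.ndarray) -> np.ndarray:
    """Age-dependent population mean for a numeric variable (synthetic values)."""
    a = np.asarray(age_years, dtype=float)
    if variable == "heart_rate":
        return 135.0 - 25.0 * np.log10(1.0 + a)
    if variable == "resp_rate":
        return 16.0 + 28.0 * np.exp(-a / 3.0)
    if variable == "spo2":
        return np.full_like(a, 98.0)
    if variable == "sbp":
        return np.minimum(85.0 + 2.2 * a, 120.0)
    if variable == "dbp":
        return np.minimum(50.0 + 1.2 * a, 75.0)
    if variable == "temp":
        return np.full_like(a, 37.0)
    if variable == "bilirubin":
        return np.full_like(a, 0.7)
    if variable == "creatinine":
        return 0.30 + 0.02 * a
    if variable == "wbc":
        return np.full_like(a, 9.0)
    raise KeyError(f"unknown variable {variable!r}")


VITAL_SIGMA = {
    "heart_rate": 12.0,
    "resp_rate": 5.0,
    "spo2": 1.5,
    "sbp": 10.0,
    "dbp": 8.0,
    "temp": 0.4,
    "bilirubin": 0.4,
    "creatinine": 0.15,
    "wbc": 3.0,
}

#: per-unit-drift effect on each drifting variable (added as ``coef * w``)
DRIFT_COEF = {
    "resp_rate": 10.0,
    "heart_rate": 12.0,
    "spo2": -4.0,
}

VITAL_RATE_SCALE = {  # relative sampling frequency vs obs_rate_per_hour
    "heart_rate": 1.0,
    "resp_rate": 1.0,
    "spo2": 1.0,
    "sbp": 0.7,
    "dbp": 0.7,
    "temp": 0.5,
    "bilirubin": 1 / 24.0,
    "creatinine": 1 / 24.0,
    "wbc": 1 / 24.0,
}

CATEGORICAL_VARS = {
    "heart_sounds": ("Normal", "Murmur"),
    "resp_effort": ("Normal", "Labored", "Tachypneic"),
}


def medication_names(vocab_size: int) -> list:
    return [f"med_{i:03d}" for i in range(vocab_size)]


# ---------------------------------------------------------------------------
# encounter table
# ---------------------------------------------------------------------------

def generate_encounters(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the encounter-level table (cheap; no event streams).

    Returns a frame with one row per encounter.  Internal helper columns
    (``severity``, ``decoy``, ``spo2_baseline``, ``no_vitals``) drive event
    generation and are retained for inspection; the cohort module ignores
    them.  ``diagnosis_categories`` and ``procedure_times`` are pipe-joined
    strings so the table round-trips through CSV.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    prev = config.mv_prevalence
    mv = rng.random(n) < prev

    # every outcome-dependent contrast (age, LOS, NIV, drift, medication
    # patterns) scales with the signal dial so that signal_strength = 0
    # yields exchangeable groups and a genuinely null cohort
    c = min(1.0, config.signal_strength / 3.0)

    def interp(group_value, other_value, weight_other):
        pool = weight_other * other_value + (1 - weight_other) * group_value
        return pool + c * (group_value - pool)

    mu_age_mv = interp(math.log(1.2), math.log(4.8), 1 - prev)
    mu_age_no = interp(math.log(4.8), math.log(1.2), prev)
    sd_age_mv = interp(1.3, 1.1, 1 - prev)
    sd_age_no = interp(1.1, 1.3, prev)
    age = np.where(
        mv,
        np.exp(rng.normal(mu_age_mv, sd_age_mv, n)),
        np.exp(rng.normal(mu_age_no, sd_age_no, n)),
    )
    age = np.clip(age, 0.02, 21.0)

    gender = np.where(rng.random(n) < 0.564, "Male", "Female").astype(object)
    race = rng.choice(RACES, size=n, p=RACE_P)
    ethnicity = rng.choice(ETHNICITIES, size=n, p=ETHNICITY_P)

    weight = (2.0 * (age + 5.0)) * np.exp(rng.normal(0.0, 0.15, n))
    height = np.minimum(72.0 * (1.0 + age) ** 0.35, 185.0) * np.exp(
        rng.normal(0.0, 0.05, n)
    )

    mu_mv, sd_mv = config.los_lognormal_params["mv"]
    mu_no, sd_no = config.los_lognormal_params["no_mv"]
    los = np.where(
        mv,
        np.exp(rng.normal(interp(mu_mv, mu_no, 1 - prev), interp(sd_mv, sd_no, 1 - prev), n)),
        np.exp(rng.normal(interp(mu_no, mu_mv, prev), interp(sd_no, sd_mv, prev), n)),
    )
    los = np.maximum(los, 6 * 60.0)  # at least 6 h of stay
    los[mv] = np.maximum(los[mv], 26 * 60.0)  # room for onset >= 12 h + 12 h of MV
    discharge = np.round(los).astype(int)

    # MV onset: early in the stay, always >= 12 h except planted violators
    onset = np.full(n, np.nan)
    mv_end = np.full(n, np.nan)
    if mv.any():
        m = int(mv.sum())
        onset_rel = rng.beta(1.3, 4.0, m)
        span = np.maximum(discharge[mv] - 26 * 60.0, 60.0)
        onset_mv = 12.5 * 60.0 + onset_rel * np.minimum(span, 5 * MINUTES_PER_DAY)
        end_mv = discharge[mv] - rng.uniform(0.0, 0.08, m) * discharge[mv]
        end_mv = np.maximum(end_mv, onset_mv + 12 * 60.0 + 30.0)
        end_mv = np.minimum(end_mv, discharge[mv])
        onset[mv] = onset_mv
        mv_end[mv] = end_mv

    niv_mv, niv_no = config.niv_prevalence_by_group
    niv_pool = prev * niv_mv + (1 - prev) * niv_no
    p_niv = np.where(mv, niv_pool + c * (niv_mv - niv_pool), niv_pool + c * (niv_no - niv_pool))
    niv = rng.random(n) < p_niv

    severity = np.zeros(n)
    if mv.any():
        severity[mv] = rng.choice([1.0, 2.0, 3.0], size=int(mv.sum()), p=[0.3, 0.4, 0.3])
    decoy = (~mv) & (rng.random(n) < config.decoy_control_fraction)

    # diagnosis categories: MV cases almost always carry a required category
    diag = []
    required = ("respiratory", "cardiovascular", "sepsis")
    for i in range(n):
        cats = set(rng.choice(DIAGNOSES, size=rng.integers(1, 4), replace=False))
        if mv[i] and not cats & set(required):
            cats.add(required[int(rng.integers(0, 3))])
        diag.append(cats)

    # procedures: 0-2 per encounter at uniform times
    n_proc = rng.integers(0, 3, n)
    procedures = [
        np.sort(rng.uniform(0, discharge[i], n_proc[i])).round().astype(int).tolist()
        for i in range(n)
    ]

    # ---- planted rule violators ------------------------------------------
    r = RULE_VIOLATION_RATES
    weight[rng.random(n) < r["missing_weight"]] = np.nan
    gender[rng.random(n) < r["missing_gender"]] = None
    no_vitals = rng.random(n) < r["no_vitals"]
    trach = rng.random(n) < r["trach"]
    cyanotic = rng.random(n) < 0.02
    spo2_baseline = np.full(n, 98.0)
    low_spo2 = cyanotic & (rng.random(n) < r["cyanotic_low_spo2"] / 0.02)
    spo2_baseline[low_spo2] = 85.0
    manual_excl = rng.random(n) < r["manual_exclusion"]

    if mv.any():
        mv_idx = np.flatnonzero(mv)
        early = mv_idx[rng.random(mv_idx.size) < r["mv_early_onset"]]
        onset[early] = rng.uniform(2 * 60.0, 11 * 60.0, early.size)
        mv_end[early] = np.minimum(onset[early] + 24 * 60.0, discharge[early])
        short = mv_idx[rng.random(mv_idx.size) < r["mv_short_duration"]]
        mv_end[short] = onset[short] + rng.uniform(2 * 60.0, 11 * 60.0, short.size)
        post_proc = mv_idx[rng.random(mv_idx.size) < r["mv_post_procedure"]]
        for i in post_proc:
            procedures[i] = sorted(
                procedures[i] + [int(max(0, onset[i] - rng.uniform(5, 85)))]
            )
        no_dx = mv_idx[rng.random(mv_idx.size) < r["mv_no_required_dx"]]
        for i in no_dx:
            diag[i] = {"other"}

    onset = np.where(np.isnan(onset), np.nan, np.round(onset))
    mv_end = np.where(np.isnan(mv_end), np.nan, np.round(mv_end))

    return pd.DataFrame(
        {
            "encounter_id": [f"e{i:06d}" for i in range(n)],
            "age_years": age,
            "gender": gender,
            "race": race,
            "ethnicity": ethnicity,
            "height_cm": height,
            "weight_kg": weight,
            "admit_time": 0,
            "discharge_time": discharge,
            "mv_flag": mv,
            "mv_onset_time": onset,
            "mv_end_time": mv_end,
            "niv_flag": niv,
            "trach_flag": trach,
            "cyanotic_flag": cyanotic,
            "manual_exclusion_flag": manual_excl,
            "diagnosis_categories": ["|".join(sorted(d)) for d in diag],
            "procedure_times": ["|".join(str(t) for t in p) for p in procedures],
            "severity": severity,
            "decoy": decoy,
            "spo2_baseline": spo2_baseline,
            "no_vitals": no_vitals,
        }
    )


# ---------------------------------------------------------------------------
# observation + medication event streams
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate_per_hour: float, los: np.ndarray):
    """Event times for an inhomogeneous-by-encounter Poisson process.

    Returns (encounter row index, time) arrays; times uniform within the stay
    given the Poisson count, which is the standard order-statistics view.
    """
    lam = rate_per_hour * los / 60.0
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(los.size), counts)
    times = rng.uniform(0.0, np.repeat(los, counts))
    return idx, times


def generate_cohort(config: GeneratorConfig):
    """Generate (encounters, observations, medications) tables.

    Observations are a long table ``(encounter_id, time, variable, value)``
    with irregular timing by construction; PEWS is emitted under variable
    ``"pews"``.  Medications carry an action from {given, rate changed,
    stopped} and a per-encounter ``sequence_no``.
    """
    enc = generate_encounters(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] % (2**31))

    n = len(enc)
    los = enc["discharge_time"].to_numpy(dtype=float)
    age = enc["age_years"].to_numpy()
    onset = enc["mv_onset_time"].to_numpy(dtype=float)
    severity = enc["severity"].to_numpy()
    decoy = enc["decoy"].to_numpy()
    no_vitals = enc["no_vitals"].to_numpy()
    spo2_base = enc["spo2_baseline"].to_numpy()
    lead = config.drift_lead_hours * 60.0
    g = config.signal_strength

    decoy_center = rng.uniform(0.3, 0.7, n) * los

    eff_los = np.where(no_vitals, 0.0, los)

    def weights_for(idx: np.ndarray, times: np.ndarray) -> np.ndarray:
        # vectorized version of _drift_weight over a long event stream
        sev = severity[idx]
        ons = onset[idx]
        w = np.zeros_like(times)
        mv_sel = (sev > 0) & ~np.isnan(ons)
        if mv_sel.any():
            ramp = np.clip((times[mv_sel] - (ons[mv_sel] - lead)) / lead, 0.0, 1.0)
            w[mv_sel] = ramp * (g / 3.0) * (0.5 + 0.25 * sev[mv_sel])
        # decoy excursions are brief and weak: the resulting false positives
        # should decay after the alert rather than mimic sustained-high cases
        dec_sel = decoy[idx] & (np.abs(times - decoy_center[idx]) < 60.0)
        w[dec_sel] = 0.35 * (g / 3.0)
        return w

    frames = []

    # numeric variables
    per_enc_offset = {
        v: rng.normal(0.0, 0.4 * VITAL_SIGMA[v], n) for v in VITAL_SIGMA
    }
    for var, rel_rate in VITAL_RATE_SCALE.items():
        idx, times = _poisson_times(rng, config.obs_rate_per_hour * rel_rate, eff_los)
        base = vital_baseline(var, age[idx])
        if var == "spo2":
            base = np.minimum(base, spo2_base[idx])
        w = weights_for(idx, times)
        drift = DRIFT_COEF.get(var, 0.0) * w
        vals = base + per_enc_offset[var][idx] + rng.normal(0, VITAL_SIGMA[var], idx.size) + drift
        if var == "spo2":
            vals = np.clip(vals, 60.0, 100.0)
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": enc["encounter_id"].to_numpy()[idx],
                    "time": np.round(times).astype(int),
                    "variable": var,
                    "value": np.round(vals, 2),
                }
            )
        )

    # categorical assessments
    for var, cats in CATEGORICAL_VARS.items():
        idx, times = _poisson_times(rng, config.obs_rate_per_hour * 0.25, eff_los)
        w = weights_for(idx, times)
        u = rng.random(idx.size)
        if var == "heart_sounds":
            p_abn = np.clip(0.05 + 0.30 * w, 0, 0.9)
            vals = np.where(u < p_abn, "Murmur", "Normal")
        else:
            p_tachy = np.clip(0.03 + 0.50 * w, 0, 0.85)
            p_lab = np.clip(0.05 + 0.20 * w, 0, 0.9 - p_tachy)
            vals = np.where(u < p_tachy, "Tachypneic", np.where(u < p_tachy + p_lab, "Labored", "Normal"))
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": enc["encounter_id"].to_numpy()[idx],
                    "time": np.round(times).astype(int),
                    "variable": var,
                    "value": vals,
                }
            )
        )

    # intake/output volumes (mL per event)
    for var, base_med, drift_mult in (("iv_volume", 40.0, 2.0), ("urine_volume", 60.0, -0.3)):
        idx, times = _poisson_times(rng, config.obs_rate_per_hour * 0.5, eff_los)
        w = weights_for(idx, times)
        vol = base_med * np.exp(rng.normal(0, 0.4, idx.size)) * np.maximum(1.0 + drift_mult * w, 0.1)
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": enc["encounter_id"].to_numpy()[idx],
                    "time": np.round(times).astype(int),
                    "variable": var,
                    "value": np.round(vol, 1),
                }
            )
        )

    # PEWS (integer 0-9, nursing score supplied as data)
    idx, times = _poisson_times(rng, 0.25, eff_los)
    w = weights_for(idx, times)
    pews = rng.poisson(1.8, idx.size) + np.round(4.0 * w).astype(int)
    pews = np.clip(pews, 0, 9)
    frames.append(
        pd.DataFrame(
            {
                "encounter_id": enc["encounter_id"].to_numpy()[idx],
                "time": np.round(times).astype(int),
                "variable": "pews",
                "value": pews,
            }
        )
    )

    observations = pd.concat(frames, ignore_index=True)
    observations = observations.sort_values(
        ["encounter_id", "time"], kind="mergesort"
    ).reset_index(drop=True)

    medications = _generate_medications(
        config, rng, enc["encounter_id"].to_numpy(), los, onset, severity, g
    )
    return enc, observations, medications


def _generate_medications(config, rng, enc_ids, los, onset, severity, g):
    """First-order chain over (medication, action) tokens.

    In the 12 h before MV onset the medication distribution is mixed toward
    the predictive subset (mixing weight 1 - exp(-g * severity / 6)) and
    repeated predictive medications escalate to "rate changed" with raised
    probability, planting ordered patterns for the sentence model to learn.
    """
    meds = medication_names(config.med_vocab_size)
    n_pred = config.n_predictive_meds
    # Zipf-ish background usage
    base_p = 1.0 / (np.arange(config.med_vocab_size) + 3.0)
    base_p /= base_p.sum()

    rows_enc, rows_time, rows_med, rows_act, rows_seq = [], [], [], [], []
    for i in range(enc_ids.size):
        lam = config.med_event_rate_per_hour * los[i] / 60.0
        k = rng.poisson(lam)
        if k == 0:
            continue
        times = np.sort(rng.uniform(0.0, los[i], k))
        in_window = (
            np.zeros(k, bool)
            if math.isnan(onset[i])
            else (times >= onset[i] - 12 * 60.0) & (times < onset[i])
        )
        mix = 0.0 if severity[i] == 0 else 1.0 - math.exp(-g * severity[i] / 6.0)
        prev_med = -1
        prev_act = "given"
        for j in range(k):
            repeat = prev_med >= 0 and rng.random() < 0.35
            if repeat:
                med = prev_med
            elif in_window[j] and rng.random() < mix and n_pred > 0:
                med = int(rng.integers(0, n_pred))
            else:
                med = int(rng.choice(config.med_vocab_size, p=base_p))
            if med == prev_med:
                boost = 0.25 * min(1.0, g / 3.0)
                esc = 0.55 + boost if (in_window[j] and med < n_pred and severity[i] > 0) else 0.55
                u = rng.random()
                act = "rate changed" if u < esc else ("stopped" if u < esc + 0.25 else "given")
            else:
                u = rng.random()
                act = "given" if u < 0.90 else ("rate changed" if u < 0.95 else "stopped")
            rows_enc.append(enc_ids[i])
            rows_time.append(int(round(times[j])))
            rows_med.append(meds[med])
            rows_act.append(act)
            rows_seq.append(j)
            prev_med, prev_act = med, act

    return pd.DataFrame(
        {
            "encounter_id": rows_enc,
            "time": rows_time,
            "medication": rows_med,
            "action": rows_act,
            "sequence_no": rows_seq,
        }
    )


# ---------------------------------------------------------------------------
# trajectory fixture bundles
# ---------------------------------------------------------------------------

#: qualitative post-alert archetype shapes: sustained-high, sustained-medium,
#: and a decaying low curve; additional archetypes interpolate between levels.
def _archetype_curve(level: int, n_archetypes: int, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points)
    if n_archetypes == 1:
        return np.full(n_points, 0.6)
    frac = level / (n_archetypes - 1)  # 0 = lowest, 1 = highest
    if frac >= 0.99:
        return np.full(n_points, 0.9)
    if level == 0:
        return 0.45 * np.exp(-2.2 * t) + 0.05
    return np.full(n_points, 0.3 + 0.6 * frac)


def generate_trajectory_bundles(
    n_per_bundle: int,
    archetypes: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_points: int = 73,
):
    """Risk-trajectory fixture: ``archetypes`` bundles of noisy mean curves.

    Returns ``(X, labels)`` with ``X`` of shape ``(archetypes * n_per_bundle,
    n_points)`` clipped to [0, 1] and integer planted labels ordered from the
    lowest archetype upward.
    """
    if archetypes < 1:
        raise ValueError("archetypes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_per_bundle < 1:
        raise ValueError("n_per_bundle must be >= 1")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for a in range(archetypes):
        mean = _archetype_curve(a, archetypes, n_points)
        block = mean[None, :] + rng.normal(0.0, noise_sd, (n_per_bundle, n_points))
        rows.append(block)
        labels.extend([a] * n_per_bundle)
    X = np.clip(np.vstack(rows), 0.0, 1.0)
    return X, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(outdir, encounters, observations, medications, fmt: str = "csv"):
    """Write the three event tables as encounters/observations/medications."""
    import os

    os.makedirs(outdir, exist_ok=True)
    tables = {
        "encounters": encounters,
        "observations": observations,
        "medications": medications,
    }
    for name, df in tables.items():
        if fmt == "csv":
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        elif fmt == "parquet":
            df.to_parquet(os.path.join(outdir, f"{name}.parquet"), index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_cohort(indir, fmt: str = "csv"):
    import os

    out = []
    for name in ("encounters", "observations", "medications"):
        path = os.path.join(indir, f"{name}.{fmt}")
        df = pd.read_csv(path) if fmt == "csv" else pd.read_parquet(path)
        out.append(df)
    enc = out[0]
    for col in ("diagnosis_categories", "procedure_times"):
        if col in enc.columns:
            enc[col] = enc[col].fillna("")
    return tuple(out)
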
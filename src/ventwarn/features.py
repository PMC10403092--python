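"""Feature engineering on the 5-minute grid.

Irregular EHR observations are resampled to a regular 5-minute grid by
last-observation-carried-forward (LOCF), categorical assessments are one-hot
encoded, physiologic numerics are standardized to age/gender z-scores against
a normal-range table, intake/output volumes become trailing 6-hour rates, and
medications become trailing 6-hour binary indicators.  Median imputation is
provided for the linear-model path only; the tree-ensemble path consumes
missingness natively.

All windows are half-open ``(t - w, t]``; the grid is left-anchored at
admission (t = 0).  Each LOCF series carries a companion ``__missing``
indicator column: sparse labs are drawn on sicker patients, so missingness is
itself informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .cohort import label_mv_prep

logger = logging.getLogger(__name__)

GRID_STEP_MINUTES = 5
IO_WINDOW_MINUTES = 360
MED_WINDOW_MINUTES = 360
POSITIVE_WINDOW_MINUTES = 720  # 12 h of samples before prep label positive


@dataclass
class FeatureDictionary:
    """Names and types of grid features; the default mirrors the synthetic
    generator's variables (a compact stand-in for a full EHR dictionary)."""

    numeric_vars: tuple = (
        "heart_rate",
        "resp_rate",
        "spo2",
        "sbp",
        "dbp",
        "temp",
        "bilirubin",
        "creatinine",
        "wbc",
    )
    zscored_vars: tuple = (
        "heart_rate",
        "resp_rate",
        "sbp",
        "dbp",
        "temp",
        "bilirubin",
        "creatinine",
        "wbc",
    )
    categorical_vars: dict = field(
        default_factory=lambda: {
            "heart_sounds": ("Normal", "Murmur"),
            "resp_effort": ("Normal", "Labored", "Tachypneic"),
        }
    )
    io_vars: dict = field(
        default_factory=lambda: {"iv_volume": "iv_rate", "urine_volume": "urine_rate"}
    )


# ---------------------------------------------------------------------------
# normal-range table
# ---------------------------------------------------------------------------

AGE_BANDS = ((0.0, 1.0), (1.0, 5.0), (5.0, 12.0), (12.0, 21.0001))


def default_normal_ranges() -> pd.DataFrame:
    """Synthetic normal-range table (variable, age band, gender, mu, sigma).

    Values are generated from the same age-dependent baselines the synthetic
    cohort uses, evaluated at band midpoints; a site deploying on real data
    supplies its own table (e.g. Harriet Lane reference ranges) via
    :func:`read_normal_ranges`.
    """
    rows = []
    for var in (
        "heart_rate",
        "resp_rate",
        "spo2",
        "sbp",
        "dbp",
        "temp",
        "bilirubin",
        "creatinine",
        "wbc",
    ):
        for lo, hi in AGE_BANDS:
            mid = np.array([(lo + min(hi, 21.0)) / 2.0])
            mu = float(synthetic.vital_baseline(var, mid)[0])
            rows.append((var, lo, hi, "any", mu, synthetic.VITAL_SIGMA[var]))
    for lo, hi in AGE_BANDS:
        mid = (lo + min(hi, 21.0)) / 2.0
        mu_w = 2.0 * (mid + 5.0)
        rows.append(("weight_kg", lo, hi, "any", mu_w, 0.15 * mu_w))
        mu_h = min(72.0 * (1.0 + mid) ** 0.35, 185.0)
        rows.append(("height_cm", lo, hi, "any", mu_h, 0.05 * mu_h))
    return pd.DataFrame(
        rows, columns=["variable", "age_low", "age_high", "gender", "mu", "sigma"]
    )


def read_normal_ranges(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    expected = {"variable", "age_low", "age_high", "gender", "mu", "sigma"}
    missing = expected - set(table.columns)
    if missing:
        raise KeyError(f"normal-range table missing columns {sorted(missing)}")
    if (table["sigma"] <= 0).any():
        raise ValueError("normal-range table sigma values must be positive")
    return table


def zscore_physiologic(value, variable, age, gender, table: pd.DataFrame):
    """z = (x - mu) / sigma with (mu, sigma) from the age/gender-matched row.

    A row matches when its age interval contains ``age`` (left-closed) and its
    gender is ``"any"`` or equals ``gender``.  Missing values map to NaN,
    except the caller's convention for height (z = 0) which is applied at
    grid-building time.
    """
    rows = table[
        (table["variable"] == variable)
        & (table["age_low"] <= age)
        & (age < table["age_high"])
        & (table["gender"].isin(["any", gender]))
    ]
    if rows.empty:
        raise LookupError(f"no normal range for variable={variable!r} age={age}")
    specific = rows[rows["gender"] != "any"]
    row = specific.iloc[0] if len(specific) else rows.iloc[0]
    return (value - row["mu"]) / row["sigma"]


def _mu_sigma_arrays(table, variable, ages, genders=None):
    """Vectorized (mu, sigma) lookup for one variable over an age array."""
    sub = table[table["variable"] == variable]
    if sub.empty:
        raise LookupError(f"no normal range for variable={variable!r}")
    mu = np.full(ages.shape, np.nan)
    sigma = np.full(ages.shape, np.nan)
    for _, row in sub.iterrows():
        sel = (row["age_low"] <= ages) & (ages < row["age_high"])
        if row["gender"] != "any" and genders is not None:
            sel &= genders == row["gender"]
        mu[sel] = row["mu"]
        sigma[sel] = row["sigma"]
    if np.isnan(mu).any():
        bad = ages[np.isnan(mu)][:3]
        raise LookupError(f"no normal range for variable={variable!r} ages={bad}")
    return mu, sigma


# ---------------------------------------------------------------------------
# LOCF resampling
# ---------------------------------------------------------------------------

def resample_locf(times, values, grid_times):
    """Carry the last observation at or before each grid time forward.

    ``times`` need not be sorted; ties keep the last value in input
    (sequence) order.  Grid points before the first observation are NaN for
    numeric input, None for object input.
    """
    times = np.asarray(times, dtype=float)
    grid_times = np.asarray(grid_times, dtype=float)
    values = np.asarray(values)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    # conflicting duplicates: keep last in sequence order
    if times.size > 1 and (np.diff(times) == 0).any():
        keep = np.r_[np.diff(times) != 0, True]
        if values[~keep].size:
            logger.debug("LOCF: %d duplicate-time observations dropped", (~keep).sum())
        times, values = times[keep], values[keep]
    pos = np.searchsorted(times, grid_times, side="right") - 1
    if np.issubdtype(values.dtype, np.number):
        out = np.full(grid_times.shape, np.nan)
    else:
        out = np.full(grid_times.shape, None, dtype=object)
    seen = pos >= 0
    out[seen] = values[pos[seen]]
    return out


def one_hot(series, categories):
    """Expand a categorical series into binary columns (one per category).

    Values outside ``categories`` (unseen at training time) and missing
    values produce an all-zero row; unseen values are logged.
    """
    arr = pd.Series(series, dtype=object)
    cats = list(categories)
    unseen = arr.dropna()[~arr.dropna().isin(cats)]
    if len(unseen):
        logger.warning("one_hot: %d values outside category set %s", len(unseen), cats)
    out = pd.DataFrame(
        {c: (arr == c).astype(np.int8).to_numpy() for c in cats}, index=arr.index
    )
    return out


def decode_one_hot(frame, categories):
    """Inverse of :func:`one_hot` for seen categories; all-zero rows -> None."""
    cats = list(categories)
    vals = frame[cats].to_numpy()
    out = np.full(len(frame), None, dtype=object)
    hit = vals.sum(axis=1) > 0
    out[hit] = np.asarray(cats, dtype=object)[vals[hit].argmax(axis=1)]
    return out


# ---------------------------------------------------------------------------
# trailing-window features
# ---------------------------------------------------------------------------

def rolling_io_rate(event_times, volumes, grid_times, window_minutes=IO_WINDOW_MINUTES):
    """Trailing input/output rate (volume per hour) over ``(t - w, t]``.

    The window is truncated at admission: before ``w`` minutes of stay the
    denominator is the elapsed time.  Rate at t = 0 is defined as 0.
    """
    event_times = np.asarray(event_times, float)
    volumes = np.asarray(volumes, float)
    if (volumes < 0).any():
        raise ValueError("negative I/O volume")
    grid_times = np.asarray(grid_times, float)
    order = np.argsort(event_times, kind="stable")
    event_times, volumes = event_times[order], volumes[order]
    cum = np.concatenate([[0.0], np.cumsum(volumes)])
    hi = np.searchsorted(event_times, grid_times, side="right")
    lo = np.searchsorted(event_times, grid_times - window_minutes, side="right")
    total = cum[hi] - cum[lo]
    denom_hours = np.minimum(window_minutes, grid_times) / 60.0
    out = np.zeros(grid_times.shape)
    pos = denom_hours > 0
    out[pos] = total[pos] / denom_hours[pos]
    return out


def med_indicator(event_times, grid_times, window_minutes=MED_WINDOW_MINUTES):
    """1 iff at least one event falls in ``(t - w, t]`` for each grid time."""
    event_times = np.sort(np.asarray(event_times, float))
    grid_times = np.asarray(grid_times, float)
    hi = np.searchsorted(event_times, grid_times, side="right")
    lo = np.searchsorted(event_times, grid_times - window_minutes, side="right")
    return (hi > lo).astype(np.int8)


def select_indicator_meds(
    medications: pd.DataFrame,
    encounters: pd.DataFrame,
    mv_fraction_threshold: float = 0.10,
    prevalence_gap_threshold: float = 0.05,
):
    """Choose medications for the binary-indicator strategy (train data only).

    A medication is selected iff (a) at least 10% of MV patients received at
    least one dose, or (b) the fraction of patients with at least one "given"
    event differs between the MV and no-MV groups by more than 5 percentage
    points.
    """
    mv_ids = set(encounters.loc[encounters["mv_flag"].astype(bool), "encounter_id"])
    no_ids = set(encounters.loc[~encounters["mv_flag"].astype(bool), "encounter_id"])
    if not mv_ids:
        raise ValueError("select_indicator_meds: no MV encounters in training set")
    given = medications[medications["action"] == "given"]
    got = given.groupby("medication")["encounter_id"].agg(set)
    selected = []
    for med, ids in got.items():
        frac_mv = len(ids & mv_ids) / len(mv_ids)
        frac_no = len(ids & no_ids) / len(no_ids) if no_ids else 0.0
        if frac_mv >= mv_fraction_threshold or abs(frac_mv - frac_no) > prevalence_gap_threshold:
            selected.append(med)
    return sorted(selected)


def med_indicator_features(
    medications: pd.DataFrame,
    selected: list,
    grid: pd.DataFrame,
    window_minutes: float = MED_WINDOW_MINUTES,
) -> pd.DataFrame:
    """Binary indicator columns ``medind__<name>`` on a (encounter, time) grid."""
    out = {}
    times_by = {
        (eid, med): g["time"].to_numpy()
        for (eid, med), g in medications[medications["medication"].isin(selected)]
        .groupby(["encounter_id", "medication"])
    }
    enc_ids = grid["encounter_id"].to_numpy()
    gtimes = grid["time"].to_numpy(float)
    bounds = _group_bounds(enc_ids)
    for med in selected:
        col = np.zeros(len(grid), dtype=np.int8)
        for eid, (a, b) in bounds.items():
            key = (eid, med)
            if key in times_by:
                col[a:b] = med_indicator(times_by[key], gtimes[a:b], window_minutes)
        out[f"medind__{med}"] = col
    return pd.DataFrame(out, index=grid.index)


def _group_bounds(sorted_ids: np.ndarray) -> dict:
    """Start/stop slice bounds per id in an id-sorted array."""
    change = np.r_[0, np.flatnonzero(sorted_ids[1:] != sorted_ids[:-1]) + 1, sorted_ids.size]
    return {sorted_ids[change[i]]: (change[i], change[i + 1]) for i in range(change.size - 1)}


# ---------------------------------------------------------------------------
# median imputation (linear-model path)
# ---------------------------------------------------------------------------

def fit_medians(train_matrix: pd.DataFrame) -> pd.Series:
    med = train_matrix.median(axis=0, skipna=True)
    all_missing = med.index[med.isna()]
    if len(all_missing):
        raise ValueError(f"all-missing training columns: {list(all_missing)}")
    return med


def impute_median(matrix: pd.DataFrame, train_medians: pd.Series) -> pd.DataFrame:
    """Fill missing numeric cells with training-set medians (linear path only;
    the tree path leaves missingness intact)."""
    return matrix.fillna(train_medians)


# ---------------------------------------------------------------------------
# feature-grid assembly
# ---------------------------------------------------------------------------

def build_feature_grid(
    encounters: pd.DataFrame,
    observations: pd.DataFrame,
    medications: pd.DataFrame,
    dictionary: FeatureDictionary | None = None,
    normal_table: pd.DataFrame | None = None,
    selected_meds: list | None = None,
    grid_step: int = GRID_STEP_MINUTES,
) -> pd.DataFrame:
    """Assemble the per-encounter 5-minute feature grid.

    Returns a long frame keyed by ``(encounter_id, time)`` with a binary
    ``label`` (1 on MV rows within 12 h before the preparation time), static
    demographics, LOCF'd z-scored numerics with ``__missing`` companions,
    one-hot categoricals, trailing I/O rates, and (if ``selected_meds``)
    medication indicators.  MV grids stop at the preparation time, so no row
    lies in [prep, onset).
    """
    dictionary = dictionary or FeatureDictionary()
    normal_table = normal_table if normal_table is not None else default_normal_ranges()

    enc = encounters.reset_index(drop=True)
    grids = []
    for row in enc.itertuples(index=False):
        if bool(row.mv_flag):
            end = label_mv_prep(pd.Series(row._asdict()))
        else:
            end = float(row.discharge_time)
        times = np.arange(0, end, grid_step, dtype=np.int64)
        if times.size == 0:
            continue
        grids.append(
            pd.DataFrame({"encounter_id": row.encounter_id, "time": times})
        )
    grid = pd.concat(grids, ignore_index=True)
    grid = grid.sort_values(["encounter_id", "time"], kind="mergesort").reset_index(drop=True)

    # labels
    enc_idx = enc.set_index("encounter_id")
    mv_flag = enc_idx["mv_flag"].astype(bool)
    prep = pd.Series(np.nan, index=enc_idx.index)
    mv_ids = mv_flag[mv_flag].index
    prep[mv_ids] = enc_idx.loc[mv_ids, "mv_onset_time"].astype(float) - 30.0
    g_prep = prep.reindex(grid["encounter_id"]).to_numpy()
    label = (
        mv_flag.reindex(grid["encounter_id"]).to_numpy()
        & (grid["time"].to_numpy() >= g_prep - POSITIVE_WINDOW_MINUTES)
        & (grid["time"].to_numpy() < g_prep)
    )
    grid["label"] = label.astype(np.int8)

    ages = enc_idx["age_years"].reindex(grid["encounter_id"]).to_numpy(float)
    genders = enc_idx["gender"].reindex(grid["encounter_id"]).to_numpy(object)

    # static features
    grid["age_years"] = ages.astype(np.float32)
    grid["gender_male"] = (genders == "Male").astype(np.int8)
    grid["niv_flag"] = (
        enc_idx["niv_flag"].astype(bool).reindex(grid["encounter_id"]).to_numpy().astype(np.int8)
    )
    for var, col in (("weight_kg", "weight_z"), ("height_cm", "height_z")):
        mu, sg = _mu_sigma_arrays(normal_table, var, ages, genders)
        raw = enc_idx[var].reindex(grid["encounter_id"]).to_numpy(float)
        z = (raw - mu) / sg
        if var == "height_cm":
            z = np.where(np.isnan(z), 0.0, z)  # missing height -> z = 0
        grid[col] = z.astype(np.float32)

    obs = observations.sort_values("time", kind="mergesort")
    grid_sorted = grid[["encounter_id", "time"]].sort_values("time", kind="mergesort")

    def locf_merge(var):
        sub = obs.loc[obs["variable"] == var, ["encounter_id", "time", "value"]]
        merged = pd.merge_asof(
            grid_sorted,
            sub.rename(columns={"value": "__v"}),
            on="time",
            by="encounter_id",
            direction="backward",
        )
        return merged["__v"].to_numpy()[np.argsort(grid_sorted.index.to_numpy(), kind="stable")]

    for var in dictionary.numeric_vars:
        vals = pd.to_numeric(pd.Series(locf_merge(var)), errors="coerce").to_numpy(float)
        grid[f"{var}__missing"] = np.isnan(vals).astype(np.int8)
        if var in dictionary.zscored_vars:
            mu, sg = _mu_sigma_arrays(normal_table, var, ages, genders)
            vals = (vals - mu) / sg
        grid[var] = vals.astype(np.float32)

    for var, cats in dictionary.categorical_vars.items():
        raw = locf_merge(var)
        oh = one_hot(raw, cats)
        for c in cats:
            grid[f"{var}={c}"] = oh[c].to_numpy()
        grid[f"{var}__missing"] = pd.isna(pd.Series(raw)).to_numpy().astype(np.int8)

    # trailing I/O rates
    enc_ids_arr = grid["encounter_id"].to_numpy()
    gtimes = grid["time"].to_numpy(float)
    bounds = _group_bounds(enc_ids_arr)
    for var, colname in dictionary.io_vars.items():
        sub = observations[observations["variable"] == var]
        by_enc = {
            eid: (g["time"].to_numpy(float), pd.to_numeric(g["value"]).to_numpy(float))
            for eid, g in sub.groupby("encounter_id")
        }
        col = np.zeros(len(grid), dtype=np.float32)
        for eid, (a, b) in bounds.items():
            if eid in by_enc:
                t, v = by_enc[eid]
                col[a:b] = rolling_io_rate(t, v, gtimes[a:b])
        grid[colname] = col

    if selected_meds:
        ind = med_indicator_features(medications, selected_meds, grid)
        grid = pd.concat([grid, ind], axis=1)

    return grid


def feature_columns(grid: pd.DataFrame) -> list:
    """All model-input columns of a feature grid (excludes keys and label)."""
    return [c for c in grid.columns if c not in ("encounter_id", "time", "label")]
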
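"""Threshold selection, early prediction point / early warning time, metrics.

An encounter is predicted positive iff its risk-score series ever crosses the
selected threshold; the first crossing is the early prediction point (EPP)
and, for true positives, the time from EPP to MV onset is the early warning
time (EWT).  The operating threshold is the score value maximizing F1 (ties
broken toward the higher threshold, i.e. higher specificity).  Two
alternative alerting policies are provided: a dual-threshold scheme (a
second, higher threshold must fire within a fixed period after the first)
and a waiting-period scheme (the crossing must be sustained for a minimum
duration).  A PEWS-based comparator evaluates the same encounter-level task
from nursing early-warning scores supplied as data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class ThresholdPolicy:
    scheme: str = "single"  # single | dual_threshold | waiting_period
    tau: float = 0.5
    tau2: float | None = None
    inter_threshold_hours: float = 6.0
    wait_hours: float = 1.0

    def __post_init__(self):
        if self.scheme not in ("single", "dual_threshold", "waiting_period"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.scheme == "dual_threshold":
            if self.tau2 is None or self.tau2 < self.tau:
                raise ValueError("dual scheme requires tau2 >= tau")


@dataclass
class EvalReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    ewt_median_hours: float
    ewt_iqr_hours: tuple
    n_encounters: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ewt_iqr_hours"] = list(self.ewt_iqr_hours)
        return d


def f1_from_sens_ppv(sensitivity: float, ppv: float) -> float:
    """F1 = 2 * sens * PPV / (sens + PPV); 0 when both are 0."""
    if sensitivity + ppv == 0:
        return 0.0
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def select_threshold(scores, labels) -> float:
    """Score value maximizing F1 of the rule ``score >= tau``.

    Candidates are the unique observed scores; ties break toward the higher
    threshold (higher specificity).  Degenerate constant scores raise.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to select a threshold")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("constant scores: no threshold separates anything")
    # descending candidates; predictions score >= tau
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # at candidate tau = unique value u: predicted positives = scores >= u
    cum_tp = np.cumsum(sorted_labels)
    n_pos = labels.sum()
    # last index where sorted_scores >= u  (descending array)
    idx = np.searchsorted(-sorted_scores, -uniq, side="right") - 1
    tp = cum_tp[idx]
    pp = idx + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = tp / pp
        rec = tp / n_pos
        f1 = np.where(tp > 0, 2 * prec * rec / (prec + rec), 0.0)
    best = f1.max()
    # ties toward the higher tau: among argmax, pick the largest unique value
    return float(uniq[np.flatnonzero(f1 == best).max()])


# ---------------------------------------------------------------------------
# EPP / EWT
# ---------------------------------------------------------------------------

def compute_epp(times, scores, policy: ThresholdPolicy):
    """First alert time under the policy, or None if the encounter never
    alerts (negative encounter prediction)."""
    times = np.asarray(times, float)
    scores = np.asarray(scores, float)
    if times.size == 0:
        raise ValueError("empty risk-score series")
    above = scores >= policy.tau
    if policy.scheme == "single":
        hits = np.flatnonzero(above)
        return float(times[hits[0]]) if hits.size else None
    if policy.scheme == "dual_threshold":
        first = np.flatnonzero(above)
        if not first.size:
            return None
        window = policy.inter_threshold_hours * 60.0
        above2 = scores >= policy.tau2
        # sequential: the tau crossing must strictly precede the tau2
        # confirmation (otherwise the scheme degenerates to single-at-tau2)
        for i in first:
            ok = np.flatnonzero(
                above2 & (times > times[i]) & (times <= times[i] + window)
            )
            if ok.size:
                return float(times[ok[0]])
        return None
    # waiting_period: crossing counts only if sustained for wait_hours of
    # consecutive grid points; EPP is the first point of the sustained run
    need = policy.wait_hours * 60.0
    run_start = None
    for i in range(times.size):
        if above[i]:
            if run_start is None:
                run_start = i
            if times[i] - times[run_start] >= need:
                return float(times[run_start])
        else:
            run_start = None
    return None


def compute_ewt(epp_minutes: float, mv_onset_minutes: float) -> float:
    """Early warning time in hours between EPP and MV onset (true positives)."""
    if epp_minutes is None or math.isnan(mv_onset_minutes):
        raise ValueError("EWT requires an EPP and an MV onset time")
    return (mv_onset_minutes - epp_minutes) / 60.0


def encounter_predictions(
    score_series: pd.DataFrame, policy: ThresholdPolicy
) -> pd.DataFrame:
    """Per-encounter prediction, EPP, and max score from a long score table."""
    rows = []
    for eid, g in score_series.groupby("encounter_id", sort=True):
        t = g["time"].to_numpy(float)
        s = g["score"].to_numpy(float)
        epp = compute_epp(t, s, policy)
        rows.append((eid, epp is not None, epp, float(np.max(s))))
    return pd.DataFrame(rows, columns=["encounter_id", "predicted", "epp", "max_score"])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _ewt_summary(ewt_hours: np.ndarray):
    if ewt_hours.size == 0:
        return float("nan"), (float("nan"), float("nan"))
    med = float(np.median(ewt_hours))
    q1, q3 = np.quantile(ewt_hours, [0.25, 0.75])  # type-7 linear interpolation
    return med, (float(q1), float(q3))


def evaluate(
    predictions: pd.DataFrame, encounters: pd.DataFrame, threshold: float
) -> EvalReport:
    """Encounter-level evaluation of the alerting classifier.

    ``predictions`` is the output of :func:`encounter_predictions`.  AUROC
    and AUPRC rank encounters by maximum risk score over the scoring span;
    confusion counts come from the alert rule; the EWT distribution
    (median [IQR]) is over true positives.
    """
    if len(predictions) == 0:
        raise ValueError("empty test set")
    enc = encounters.set_index("encounter_id")
    merged = predictions.set_index("encounter_id")
    y = enc.loc[merged.index, "mv_flag"].astype(bool).to_numpy()
    pred = merged["predicted"].to_numpy(bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    f1 = f1_from_sens_ppv(
        0.0 if math.isnan(sens) else sens, 0.0 if math.isnan(ppv) else ppv
    )
    max_score = merged["max_score"].to_numpy(float)
    auroc = float(roc_auc_score(y, max_score)) if 0 < y.sum() < y.size else float("nan")
    auprc = (
        float(average_precision_score(y, max_score))
        if 0 < y.sum() < y.size
        else float("nan")
    )
    tp_ids = merged.index[pred & y]
    ewts = np.array(
        [
            compute_ewt(merged.at[i, "epp"], float(enc.at[i, "mv_onset_time"]))
            for i in tp_ids
        ]
    )
    med, iqr = _ewt_summary(ewts)
    return EvalReport(
        threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn,
        auroc=auroc, auprc=auprc,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1,
        ewt_median_hours=med, ewt_iqr_hours=iqr,
        n_encounters=len(predictions),
    )


# ---------------------------------------------------------------------------
# PEWS comparator
# ---------------------------------------------------------------------------

def pews_comparator(
    observations: pd.DataFrame,
    encounters: pd.DataFrame,
    tau_max: float = 5.0,
    tau_daily: float = 6.0,
):
    """Evaluate PEWS-based classifiers on the same encounter-level task.

    (i) max-PEWS rule: positive iff the maximum PEWS observed up to MV onset
    (cases) or over the whole stay (controls) exceeds ``tau_max``; lead time
    for true positives runs from the first PEWS above the threshold.
    (ii) daily-PEWS rule: over consecutive 24-h intervals, an interval is
    positive iff its max PEWS exceeds ``tau_daily``; its label is whether MV
    onset falls in the following 24 h.  Returns a dict with both reports.
    PEWS values are consumed as recorded data; the scoring rubric is not
    recomputed.
    """
    pews = observations[observations["variable"] == "pews"]
    if len(pews) == 0:
        import warnings

        warnings.warn("no PEWS observations; comparator skipped")
        return None
    pews = pews.assign(value=pd.to_numeric(pews["value"]))
    by_enc = {k: v for k, v in pews.groupby("encounter_id")}
    enc = encounters.reset_index(drop=True)

    rows = []
    daily_pred, daily_label, daily_max = [], [], []
    lead_times = []
    for r in enc.itertuples(index=False):
        mv = bool(r.mv_flag)
        onset = float(r.mv_onset_time) if mv else float("nan")
        horizon = onset if mv else float(r.discharge_time)
        sub = by_enc.get(r.encounter_id)
        if sub is None or len(sub) == 0:
            rows.append((r.encounter_id, False, None, 0.0))
        else:
            t = sub["time"].to_numpy(float)
            v = sub["value"].to_numpy(float)
            keep = t <= horizon
            t, v = t[keep], v[keep]
            mx = float(v.max()) if v.size else 0.0
            hits = np.flatnonzero(v > tau_max)
            epp = float(t[hits[0]]) if hits.size else None
            rows.append((r.encounter_id, epp is not None, epp, mx))
        # daily intervals over the scoring horizon
        n_days = max(1, int(math.ceil(horizon / 1440.0)))
        for d in range(n_days):
            lo, hi = d * 1440.0, (d + 1) * 1440.0
            if sub is not None and len(sub):
                m = sub[(sub["time"] >= lo) & (sub["time"] < hi)]["value"]
                mx_d = float(m.max()) if len(m) else 0.0
            else:
                mx_d = 0.0
            label_d = mv and hi <= onset <= hi + 1440.0
            daily_pred.append(mx_d > tau_daily)
            daily_label.append(bool(label_d))
            daily_max.append(mx_d)
            if label_d and mx_d > tau_daily and sub is not None:
                m = sub[(sub["time"] >= lo) & (sub["time"] < hi)]
                first = m[m["value"] > tau_daily]["time"].min()
                lead_times.append((onset - float(first)) / 60.0)

    pred_df = pd.DataFrame(rows, columns=["encounter_id", "predicted", "epp", "max_score"])
    max_report = evaluate(pred_df, enc, threshold=tau_max)

    yd = np.asarray(daily_label, bool)
    pd_arr = np.asarray(daily_pred, bool)
    sd = np.asarray(daily_max, float)
    tp = int((pd_arr & yd).sum()); fp = int((pd_arr & ~yd).sum())
    fn = int((~pd_arr & yd).sum()); tn = int((~pd_arr & ~yd).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    med, iqr = _ewt_summary(np.asarray(lead_times))
    daily_report = EvalReport(
        threshold=tau_daily,
        tp=tp, fp=fp, tn=tn, fn=fn,
        auroc=float(roc_auc_score(yd, sd)) if 0 < yd.sum() < yd.size else float("nan"),
        auprc=float(average_precision_score(yd, sd)) if 0 < yd.sum() < yd.size else float("nan"),
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        f1=f1_from_sens_ppv(sens if not math.isnan(sens) else 0.0,
                            ppv if not math.isnan(ppv) else 0.0),
        ewt_median_hours=med, ewt_iqr_hours=iqr,
        n_encounters=int(yd.size),
    )
    return {"max_pews": max_report, "daily_pews": daily_report}


def select_dual_thresholds(scores, labels, sens_retention: float = 0.9):
    """(tau, tau2) for the dual-threshold scheme: tau from max F1; tau2 the
    precision-maximizing threshold whose sensitivity stays above
    ``sens_retention`` times the sensitivity at tau."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    tau = select_threshold(scores, labels)
    base_sens = ((scores >= tau) & (labels == 1)).sum() / max(labels.sum(), 1)
    best_tau2, best_prec = tau, -1.0
    for u in np.unique(scores):
        if u < tau:
            continue
        pred = scores >= u
        tp = int((pred & (labels == 1)).sum())
        if tp == 0:
            continue
        sens = tp / labels.sum()
        if sens < sens_retention * base_sens:
            continue
        prec = tp / pred.sum()
        if prec > best_prec or (prec == best_prec and u > best_tau2):
            best_prec, best_tau2 = prec, float(u)
    return float(tau), float(best_tau2)
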
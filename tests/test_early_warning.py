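"""Threshold selection, EPP/EWT computation, metrics, PEWS comparator."""

import math

import numpy as np
import pandas as pd
import pytest

from ventwarn.early_warning import (
    EvalReport,
    ThresholdPolicy,
    compute_epp,
    compute_ewt,
    encounter_predictions,
    evaluate,
    f1_from_sens_ppv,
    pews_comparator,
    select_dual_thresholds,
    select_threshold,
)


def brute_force_threshold(scores, labels):
    """Oracle: max-F1 over all unique values and midpoints."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    candidates = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2])
    best_f1, best_tau = -1.0, None
    for tau in np.sort(candidates):
        pred = scores >= tau
        tp = int((pred & (labels == 1)).sum())
        if tp == 0:
            f1 = 0.0
        else:
            prec = tp / pred.sum()
            rec = tp / labels.sum()
            f1 = 2 * prec * rec / (prec + rec)
        if f1 >= best_f1 - 1e-12:
            if f1 > best_f1 + 1e-12 or (best_tau is not None and tau > best_tau):
                best_f1, best_tau = max(f1, best_f1), tau
    return best_f1


class TestSelectThreshold:
    def test_enumerated_example(self):
        tau = select_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert tau == 0.35
        pred = np.asarray([0.1, 0.4, 0.35, 0.8]) >= tau
        tp = (pred & np.array([0, 0, 1, 1], bool)).sum()
        f1 = 2 * (tp / pred.sum()) * (tp / 2) / ((tp / pred.sum()) + tp / 2)
        assert f1 == pytest.approx(0.8)

    def test_perfect_separation_picks_highest_tying_threshold(self):
        tau = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert tau == 0.8  # any tau in (0.2, 0.8] gives F1=1; highest candidate wins

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            select_threshold([0.2, 0.3], [1, 1])
        with pytest.raises(ValueError):
            select_threshold([0.5, 0.5], [0, 1])

    def test_matches_brute_force_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 50
            scores = rng.random(n).round(2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or np.unique(scores).size < 2:
                continue
            tau = select_threshold(scores, labels)
            pred = scores >= tau
            tp = int((pred & (labels == 1)).sum())
            f1 = 0.0 if tp == 0 else 2 * (tp / pred.sum()) * (tp / labels.sum()) / (
                tp / pred.sum() + tp / labels.sum()
            )
            assert f1 == pytest.approx(brute_force_threshold(scores, labels))


class TestEpp:
    def test_first_crossing(self):
        t = np.array([0, 5, 10, 15.0])
        s = np.array([0.1, 0.2, 0.6, 0.4])
        assert compute_epp(t, s, ThresholdPolicy(tau=0.5)) == 10.0

    def test_never_crossing_is_negative_prediction(self):
        t = np.arange(4) * 5.0
        assert compute_epp(t, np.full(4, 0.1), ThresholdPolicy(tau=0.5)) is None

    def test_immediate_crossing(self):
        t = np.arange(4) * 5.0
        s = np.array([0.9, 0.1, 0.1, 0.1])
        assert compute_epp(t, s, ThresholdPolicy(tau=0.5)) == 0.0

    def test_dual_threshold_requires_second_crossing_within_window(self):
        pol = ThresholdPolicy("dual_threshold", tau=0.5, tau2=0.8,
                              inter_threshold_hours=1.0)
        t = np.arange(0, 200, 5.0)
        s = np.full(t.size, 0.1)
        s[2] = 0.6          # tau crossing at t=10
        s[10] = 0.85        # tau2 crossing at t=50 (within 60 min)
        assert compute_epp(t, s, pol) == 50.0
        s2 = np.full(t.size, 0.1)
        s2[2] = 0.6
        s2[30] = 0.85       # tau2 at t=150 (outside 60 min)
        assert compute_epp(t, s2, pol) is None

    def test_dual_positives_subset_of_single(self):
        rng = np.random.default_rng(1)
        single = ThresholdPolicy(tau=0.6)
        dual = ThresholdPolicy("dual_threshold", tau=0.6, tau2=0.8)
        for _ in range(50):
            t = np.arange(0, 24 * 60, 5.0)
            s = np.clip(rng.normal(0.4, 0.2, t.size), 0, 1)
            e_single = compute_epp(t, s, single)
            e_dual = compute_epp(t, s, dual)
            if e_dual is not None:
                assert e_single is not None
                assert e_dual >= e_single

    def test_waiting_period_requires_sustained_run(self):
        pol = ThresholdPolicy("waiting_period", tau=0.5, wait_hours=0.5)
        t = np.arange(0, 120, 5.0)
        s = np.full(t.size, 0.1)
        s[4:6] = 0.7   # 10-minute excursion: too short
        assert compute_epp(t, s, pol) is None
        s[10:18] = 0.7  # 35-minute sustained run starting at t=50
        assert compute_epp(t, s, pol) == 50.0

    def test_threshold_sweep_monotonicity(self):
        rng = np.random.default_rng(5)
        series = []
        for i in range(40):
            t = np.arange(0, 12 * 60, 5.0)
            s = np.clip(rng.normal(0.4, 0.25, t.size), 0, 1)
            series.append((t, s, i % 2 == 0))
        prev_sens, prev_spec = 1.1, -0.1
        for tau in (0.2, 0.4, 0.6, 0.8):
            pol = ThresholdPolicy(tau=tau)
            pred = [compute_epp(t, s, pol) is not None for t, s, _ in series]
            y = [mv for _, _, mv in series]
            tp = sum(p and m for p, m in zip(pred, y))
            tn = sum((not p) and (not m) for p, m in zip(pred, y))
            sens = tp / sum(y)
            spec = tn / (len(y) - sum(y))
            assert sens <= prev_sens + 1e-12
            assert spec >= prev_spec - 1e-12
            prev_sens, prev_spec = sens, spec


class TestEwt:
    def test_arithmetic(self):
        assert compute_ewt(600.0, 1194.0) == pytest.approx(9.9)
        assert compute_ewt(1170.0 - 5, 1200.0) == pytest.approx(35 / 60)

    def test_requires_onset(self):
        with pytest.raises(ValueError):
            compute_ewt(100.0, float("nan"))


class TestEvaluate:
    def _toy(self):
        enc = pd.DataFrame(
            {
                "encounter_id": [f"e{i}" for i in range(10)],
                "mv_flag": [True, True, False, False, False, False, False,
                            False, False, False],
                "mv_onset_time": [1200.0, 1500.0] + [np.nan] * 8,
            }
        )
        preds = pd.DataFrame(
            {
                "encounter_id": [f"e{i}" for i in range(10)],
                "predicted": [True, True, True] + [False] * 7,
                "epp": [600.0, 700.0, 100.0] + [None] * 7,
                "max_score": [0.9, 0.8, 0.7, 0.3, 0.2, 0.25, 0.1, 0.15, 0.05, 0.12],
            }
        )
        return preds, enc

    def test_confusion_arithmetic(self):
        preds, enc = self._toy()
        rep = evaluate(preds, enc, threshold=0.5)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (2, 1, 0, 7)
        assert rep.ppv == pytest.approx(2 / 3)
        assert rep.sensitivity == 1.0
        assert rep.specificity == pytest.approx(7 / 8)
        assert rep.npv == 1.0
        assert rep.ewt_median_hours == pytest.approx((10 + 40 / 3) / 2, abs=0.1)

    def test_f1_identity(self):
        assert f1_from_sens_ppv(0.47, 0.54) == pytest.approx(0.50, abs=0.005)
        assert f1_from_sens_ppv(1.0, 1.0) == 1.0
        assert f1_from_sens_ppv(0.0, 0.0) == 0.0

    def test_empty_test_set_raises(self):
        _, enc = self._toy()
        with pytest.raises(ValueError):
            evaluate(pd.DataFrame(columns=["encounter_id", "predicted", "epp",
                                           "max_score"]), enc, 0.5)


class TestEncounterPredictions:
    def test_epp_and_max_per_encounter(self):
        series = pd.DataFrame(
            {
                "encounter_id": ["a"] * 3 + ["b"] * 3,
                "time": [0, 5, 10] * 2,
                "score": [0.1, 0.6, 0.2, 0.3, 0.4, 0.45],
            }
        )
        out = encounter_predictions(series, ThresholdPolicy(tau=0.5))
        out = out.set_index("encounter_id")
        assert bool(out.at["a", "predicted"]) is True
        assert out.at["a", "epp"] == 5.0
        assert bool(out.at["b", "predicted"]) is False
        assert out.at["b", "max_score"] == pytest.approx(0.45)


class TestPews:
    def _toy(self):
        enc = pd.DataFrame(
            {
                "encounter_id": [f"p{i}" for i in range(10)],
                "mv_flag": [True, True] + [False] * 8,
                "mv_onset_time": [30 * 60.0, 40 * 60.0] + [np.nan] * 8,
                "discharge_time": [80 * 60.0] * 10,
            }
        )
        rows = []
        # case p0: PEWS 7 at 10 h -> max-PEWS positive (TP), lead 20 h
        rows += [("p0", 600, "pews", 7)]
        # case p1: PEWS max 4 -> missed (FN)
        rows += [("p1", 600, "pews", 4)]
        # control p2: PEWS 7 once -> false positive
        rows += [("p2", 1200, "pews", 7)]
        # controls p3..p9: low PEWS
        rows += [(f"p{i}", 600, "pews", 2) for i in range(3, 10)]
        obs = pd.DataFrame(rows, columns=["encounter_id", "time", "variable", "value"])
        return obs, enc

    def test_max_pews_confusion_matches_hand_count(self):
        obs, enc = self._toy()
        reports = pews_comparator(obs, enc, tau_max=5, tau_daily=6)
        rep = reports["max_pews"]
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (1, 1, 1, 7)
        assert rep.ewt_median_hours == pytest.approx(20.0)

    def test_case_below_threshold_is_negative(self):
        obs, enc = self._toy()
        rep = pews_comparator(obs, enc, tau_max=7)["max_pews"]
        assert rep.tp == 0  # max PEWS 7 is not > 7

    def test_missing_pews_stream_warns_and_skips(self):
        _, enc = self._toy()
        empty = pd.DataFrame(columns=["encounter_id", "time", "variable", "value"])
        with pytest.warns(UserWarning):
            assert pews_comparator(empty, enc) is None


class TestDualSelection:
    def test_tau2_at_least_tau_and_retains_sensitivity(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.uniform(0, 0.6, 80), rng.uniform(0.4, 1.0, 20)])
        labels = np.concatenate([np.zeros(80, int), np.ones(20, int)])
        tau, tau2 = select_dual_thresholds(scores, labels)
        assert tau2 >= tau
        base_sens = ((scores >= tau) & (labels == 1)).mean() / labels.mean()
        sens2 = ((scores >= tau2) & (labels == 1)).sum() / labels.sum()
        assert sens2 >= 0.9 * base_sens - 1e-9
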
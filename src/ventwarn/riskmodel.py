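"""Risk-score models: feature-set assembly, balanced sampling, fitting, scoring.

Four feature sets are compared: A = non-medication + medication-history
(medhist) features, B = non-medication + medication indicators, C =
non-medication only, D = medhist only.  The default learner is a
gradient-boosted tree ensemble (XGBoost) that consumes missing values
natively; an L1-regularized logistic regression (on the median-imputed
matrix) is the linear comparator.

Training instances are class-balanced: every grid row in the 12 hours before
the MV-preparation time of each case, plus an equal number of rows drawn
uniformly without replacement from the no-MV encounters.  Rows in
[prep, onset) never exist on the grid, so neither training nor scoring can
leak the intubation period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

logger = logging.getLogger(__name__)

POSITIVE_WINDOW_MINUTES = 720

MODEL_BLOCKS = {
    "A": ("clinical", "medhist"),
    "B": ("clinical", "medind"),
    "C": ("clinical",),
    "D": ("medhist",),
}

DEFAULT_GBT_PARAMS = {
    "max_depth": 6,
    "min_child_weight": 1,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "eta": 0.1,
    "objective": "binary:logistic",
    "eval_metric": "auc",
    "tree_method": "hist",
    "nthread": 1,
}
DEFAULT_ROUNDS = 200
EARLY_STOPPING_ROUNDS = 20


@dataclass
class ModelSpec:
    model_id: str = "A"
    learner: str = "gbt"  # or "l1_logistic"
    params: dict = field(default_factory=dict)
    n_rounds: int = DEFAULT_ROUNDS
    seed: int = 0

    def __post_init__(self):
        if self.model_id not in MODEL_BLOCKS:
            raise ValueError(f"model_id must be one of {sorted(MODEL_BLOCKS)}")
        if self.learner not in ("gbt", "l1_logistic"):
            raise ValueError("learner must be 'gbt' or 'l1_logistic'")

    @property
    def blocks(self) -> tuple:
        return MODEL_BLOCKS[self.model_id]


def block_columns(columns, blocks) -> list:
    """Partition grid columns into feature blocks and select the given ones."""
    out = []
    for c in columns:
        if c in ("encounter_id", "time", "label"):
            continue
        if c.startswith("medhist"):
            blk = "medhist"
        elif c.startswith("medind__"):
            blk = "medind"
        else:
            blk = "clinical"
        if blk in blocks:
            out.append(c)
    return out


def sample_training_instances(
    grid: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Balanced instance table from training-split feature grids.

    Positives: all grid rows with label 1 (the 12 h before each MV case's
    preparation time).  Negatives: an equal number of rows sampled uniformly
    without replacement across all no-MV rows.  Deterministic given seed.
    """
    pos = grid[grid["label"] == 1]
    # negatives come from no-MV encounters only; early rows of MV cases are
    # neither positive nor eligible negatives
    mv_encounters = set(pos["encounter_id"])
    neg_pool = grid[(grid["label"] == 0) & ~grid["encounter_id"].isin(mv_encounters)]
    n_pos = len(pos)
    if n_pos == 0:
        raise ValueError("no positive rows to sample")
    if len(neg_pool) < n_pos:
        raise ValueError(
            f"insufficient negative rows: need {n_pos}, have {len(neg_pool)}"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(neg_pool), size=n_pos, replace=False)
    neg = neg_pool.iloc[np.sort(take)]
    out = pd.concat([pos, neg], ignore_index=True)
    return out


class FittedModel:
    """A fitted scorer emitting class-1 probabilities on feature frames."""

    def __init__(self, spec: ModelSpec, feature_names: list):
        self.spec = spec
        self.feature_names = list(feature_names)
        self.booster = None
        self.linear = None
        self.train_medians = None
        self.best_iteration = None
        self.chance_level = False  # validation AUC indistinguishable from 0.5

    def _check_columns(self, frame: pd.DataFrame):
        missing = [c for c in self.feature_names if c not in frame.columns]
        if missing:
            raise KeyError(f"feature columns missing at scoring time: {missing}")

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        self._check_columns(frame)
        if self.chance_level:
            return np.full(len(frame), 0.5)
        X = frame[self.feature_names]
        if self.booster is not None:
            dm = xgb.DMatrix(X, missing=np.nan, feature_names=self.feature_names)
            kwargs = {}
            if self.best_iteration is not None:
                kwargs["iteration_range"] = (0, self.best_iteration + 1)
            return self.booster.predict(dm, **kwargs)
        X = X.fillna(self.train_medians)
        return self.linear.predict_proba(X.to_numpy(float))[:, 1]


def fit(spec: ModelSpec, instances: pd.DataFrame, feature_names=None) -> FittedModel:
    """Fit the learner named by the spec on a balanced instance table.

    The tree path trains with a seeded 10% stratified validation split and
    AUC early stopping (capped at ``n_rounds``), then scores with the best
    iteration.  The linear path median-imputes on training data and selects
    the L1 penalty by cross-validation.
    """
    y = instances["label"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if feature_names is None:
        feature_names = block_columns(instances.columns, spec.blocks)
    model = FittedModel(spec, feature_names)
    X = instances[feature_names]

    if spec.learner == "gbt":
        from sklearn.model_selection import train_test_split

        idx_tr, idx_va = train_test_split(
            np.arange(len(y)),
            test_size=0.1,
            stratify=y,
            random_state=spec.seed,
        )
        params = {**DEFAULT_GBT_PARAMS, **spec.params, "seed": spec.seed}
        dtr = xgb.DMatrix(X.iloc[idx_tr], label=y[idx_tr], missing=np.nan,
                          feature_names=feature_names)
        dva = xgb.DMatrix(X.iloc[idx_va], label=y[idx_va], missing=np.nan,
                          feature_names=feature_names)
        booster = xgb.train(
            params,
            dtr,
            num_boost_round=spec.n_rounds,
            evals=[(dva, "valid")],
            early_stopping_rounds=EARLY_STOPPING_ROUNDS,
            verbose_eval=False,
        )
        model.booster = booster
        model.best_iteration = getattr(booster, "best_iteration", None)
        # chance-level guard: a model whose best validation AUC is not
        # significantly above 0.5 has found nothing; deploying it would only
        # add noise (and, through per-encounter maxima, bias toward whichever
        # group is scored over more rows).  Hanley-McNeil null SE, 3-sigma.
        n1 = int(y[idx_va].sum())
        n0 = int(len(idx_va) - n1)
        if n1 > 0 and n0 > 0:
            se = float(np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0)))
            best = float(getattr(booster, "best_score", 1.0))
            if best < 0.5 + 3.0 * se:
                logger.info(
                    "validation AUC %.3f indistinguishable from chance; "
                    "deploying constant prior", best,
                )
                model.chance_level = True
    else:
        from sklearn.linear_model import LogisticRegressionCV

        from .features import fit_medians

        med = fit_medians(X)
        model.train_medians = med
        Xi = X.fillna(med).to_numpy(float)
        model.linear = LogisticRegressionCV(
            Cs=10,
            cv=10,
            penalty="l1",
            solver="liblinear",
            scoring="roc_auc",
            random_state=spec.seed,
            max_iter=2000,
        ).fit(Xi, y)
    return model


def score_series(model: FittedModel, grid: pd.DataFrame) -> pd.DataFrame:
    """Risk-score series: one probability per retained grid row.

    Returns ``(encounter_id, time, score)`` covering admission to prep time
    for MV encounters and the full stay for controls (the grid's span).
    """
    scores = model.predict(grid)
    return pd.DataFrame(
        {
            "encounter_id": grid["encounter_id"].to_numpy(),
            "time": grid["time"].to_numpy(),
            "score": scores.astype(float),
        }
    )


def feature_importance(model: FittedModel, instances: pd.DataFrame) -> pd.DataFrame:
    """Per-feature split gain and mean |SHAP| over training rows, ranked.

    Gain is the tree ensemble's split-gain attribution (0 for features never
    used in a split); SHAP values come from TreeSHAP (xgboost
    ``pred_contribs``) and satisfy per-row additivity to the model margin.
    For a non-tree model gain is unavailable (NaN) and SHAP is not computed
    here.
    """
    names = model.feature_names
    if model.booster is None:
        raise ValueError("feature_importance requires a tree-ensemble model")
    gain_raw = model.booster.get_score(importance_type="gain")
    total = sum(gain_raw.values()) or 1.0
    gain = np.array([gain_raw.get(n, 0.0) / total for n in names])

    dm = xgb.DMatrix(instances[names], missing=np.nan, feature_names=names)
    contribs = model.booster.predict(
        dm, pred_contribs=True,
        iteration_range=(0, (model.best_iteration or 0) + 1),
    )
    mean_abs_shap = np.abs(contribs[:, :-1]).mean(axis=0)  # last col = bias

    out = pd.DataFrame(
        {"feature": names, "gain": gain, "mean_abs_shap": mean_abs_shap}
    )
    return out.sort_values("mean_abs_shap", ascending=False).reset_index(drop=True)


def shap_additivity_check(model: FittedModel, instances: pd.DataFrame) -> float:
    """Max |sum(contribs) - margin| over rows (TreeSHAP additivity)."""
    names = model.feature_names
    dm = xgb.DMatrix(instances[names], missing=np.nan, feature_names=names)
    rng = (0, (model.best_iteration or 0) + 1)
    contribs = model.booster.predict(dm, pred_contribs=True, iteration_range=rng)
    margin = model.booster.predict(dm, output_margin=True, iteration_range=rng)
    return float(np.abs(contribs.sum(axis=1) - margin).max())
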
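"""End-to-end experiment orchestration.

``run_all`` wires the stages together: synthetic cohort -> inclusion/
exclusion -> stratified split -> medication selection and medication-history
extractor training (train split only) -> 5-minute feature grid -> balanced
instance sampling -> model fitting per feature set (A/B/C/D) -> threshold
selection on the training encounters -> encounter-level evaluation with
EPP/EWT on the held-out test encounters -> spectral risk grouping of the
best model's positive predictions -> PEWS comparator -> JSON reports.

Every stochastic stage draws its seed deterministically from the single
global seed, so a config fully determines the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import early_warning as ew
from . import features as feat_mod
from . import medsent, risk_groups, riskmodel
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = None
    filter: cohort_mod.CohortFilterConfig = None
    conv: medsent.ConvExtractorConfig = None
    models: tuple = ("A", "B", "C", "D")
    learner: str = "gbt"
    glove_window: int = 25
    glove_dim: int = 10
    glove_epochs: int = 30
    run_b_variants: bool = False
    model_cv_folds: int = 10
    risk_group_model: str = "A"
    knn_K: int | None = None  # None -> min(200, max(10, n_trajectories // 4))
    k_max: int = 8
    k_nn: int = 15
    n_boot: int = 50
    run_cnn_cv: bool = True

    def __post_init__(self):
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if self.filter is None:
            self.filter = cohort_mod.CohortFilterConfig()
        if self.conv is None:
            self.conv = medsent.ConvExtractorConfig(seed=self.seed)


def _child_seeds(seed: int, n: int = 16) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n)]


def run_all(config: RunConfig, outdir=None, return_internals: bool = False) -> dict:
    """Run the full experiment; return (and optionally write) the reports.

    The result dict has per-model evaluation reports (threshold, confusion
    counts, AUROC/AUPRC/sens/spec/PPV/NPV/F1, EWT median [IQR]), the risk
    group table (per-group n, PPV, EWT), top-feature importance tables,
    the PEWS comparator reports, and a manifest (config hash, versions).
    """
    seeds = _child_seeds(config.seed)
    need_medhist = any(m in ("A", "D") for m in config.models)
    need_medind = "B" in config.models or config.run_b_variants

    # 1. cohort generation ---------------------------------------------------
    gen_cfg = dataclasses.replace(config.generator)
    encounters, observations, medications = generate_cohort(gen_cfg)
    logger.info("generated %d encounters (%d MV)", len(encounters),
                int(encounters["mv_flag"].sum()))

    # 2. inclusion/exclusion and split ---------------------------------------
    retained, exclusion_log = cohort_mod.apply_inclusion_exclusion(
        encounters, observations, config.filter
    )
    train_ids, test_ids = cohort_mod.stratified_split(retained, 0.8, seed=seeds[1])
    train_enc = retained[retained["encounter_id"].isin(train_ids)].reset_index(drop=True)
    test_enc = retained[retained["encounter_id"].isin(test_ids)].reset_index(drop=True)

    # 3. train-only fits: medication selection, embeddings, CNN --------------
    train_meds = medications[medications["encounter_id"].isin(train_ids)]
    selected_meds = None
    if need_medind:
        selected_meds = feat_mod.select_indicator_meds(train_meds, train_enc)
        logger.info("selected %d indicator medications", len(selected_meds))

    extractor = None
    if need_medhist:
        sentences, labels = medsent.build_training_corpus(train_meds, train_enc)
        embeddings = medsent.fit_embeddings(
            sentences,
            window=config.glove_window,
            dim=config.glove_dim,
            epochs=config.glove_epochs,
            seed=seeds[2],
        )
        conv_cfg = dataclasses.replace(config.conv, seed=seeds[3])
        extractor = medsent.train_extractor(
            sentences, labels, conv_cfg, embeddings, run_cv=config.run_cnn_cv
        )
        if extractor.cv_scores_:
            logger.info("CNN CV AUROC: %.3f", float(np.mean(extractor.cv_scores_)))

    # 4. feature grid --------------------------------------------------------
    grid = feat_mod.build_feature_grid(
        retained, observations, medications, selected_meds=selected_meds
    )
    if extractor is not None:
        mh = medsent.medhist_grid_features(extractor, medications, grid)
        grid = pd.concat([grid, mh], axis=1)
    is_train_row = grid["encounter_id"].isin(train_ids).to_numpy()
    train_grid = grid[is_train_row]
    test_grid = grid[~is_train_row]

    # 5. models --------------------------------------------------------------
    results: dict = {"models": {}, "manifest": _manifest(config)}
    fitted: dict = {}
    series: dict = {}
    for i, model_id in enumerate(config.models):
        spec = riskmodel.ModelSpec(
            model_id=model_id, learner=config.learner, seed=seeds[4] + i
        )
        instances = riskmodel.sample_training_instances(train_grid, seed=seeds[5] + i)
        model = riskmodel.fit(spec, instances)
        fitted[model_id] = (model, instances)

        # out-of-fold risk scores on the training course: the threshold (and
        # the training trajectories) must not come from in-sample scores,
        # which are optimistically high
        train_series = _cv_train_scores(
            spec, train_grid, train_enc, config.model_cv_folds, seeds[5] + i
        )
        test_series = riskmodel.score_series(model, test_grid)
        series[model_id] = (train_series, test_series)

        train_pred_max = train_series.groupby("encounter_id")["score"].max()
        train_labels = (
            train_enc.set_index("encounter_id")["mv_flag"]
            .astype(bool)
            .reindex(train_pred_max.index)
            .to_numpy()
            .astype(int)
        )
        try:
            tau = ew.select_threshold(train_pred_max.to_numpy(), train_labels)
        except ValueError:
            # degenerate (e.g. chance-level constant scores): alerts off
            logger.warning("threshold selection degenerate for model %s", model_id)
            tau = 0.99
        policy = ew.ThresholdPolicy(scheme="single", tau=tau)
        preds = ew.encounter_predictions(test_series, policy)
        report = ew.evaluate(preds, test_enc, threshold=tau)
        entry = {"report": report.to_dict(), "policy": dataclasses.asdict(policy)}
        if model.booster is not None:
            imp = riskmodel.feature_importance(model, instances)
            entry["importance_top20"] = imp.head(20).to_dict(orient="records")
        results["models"][model_id] = entry

        if config.run_b_variants and model_id == "B":
            tau_b, tau2 = ew.select_dual_thresholds(
                train_pred_max.to_numpy(), train_labels
            )
            for variant, pol in (
                ("B1", ew.ThresholdPolicy("dual_threshold", tau=tau_b, tau2=tau2)),
                ("B2", ew.ThresholdPolicy("waiting_period", tau=tau_b)),
            ):
                p = ew.encounter_predictions(test_series, pol)
                rep = ew.evaluate(p, test_enc, threshold=pol.tau)
                results["models"][variant] = {
                    "report": rep.to_dict(),
                    "policy": dataclasses.asdict(pol),
                }

    # 6. risk grouping on the configured model -------------------------------
    rg_id = config.risk_group_model
    if rg_id in series:
        train_series, test_series = series[rg_id]
        tau = results["models"][rg_id]["policy"]["tau"]
        policy = ew.ThresholdPolicy(scheme="single", tau=tau)
        train_preds = ew.encounter_predictions(train_series, policy)
        try:
            results["risk_groups"] = _risk_group_stage(
                config, train_preds, train_series, test_series,
                train_enc, test_enc, policy, seeds,
            )
        except ValueError as exc:
            logger.warning("risk grouping skipped: %s", exc)
            results["risk_groups"] = {"error": str(exc)}

    # 7. PEWS comparator on the test split -----------------------------------
    pews = ew.pews_comparator(
        observations[observations["encounter_id"].isin(test_ids)], test_enc
    )
    if pews is not None:
        results["pews"] = {k: v.to_dict() for k, v in pews.items()}

    results["cohort"] = {
        "n_input": int(len(encounters)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(exclusion_log)),
        "mv_prevalence": float(retained["mv_flag"].mean()),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
    }

    if return_internals:
        results["_internals"] = {
            "grid": grid,
            "series": series,
            "retained": retained,
            "train_ids": train_ids,
            "test_ids": test_ids,
            "train_enc": train_enc,
            "test_enc": test_enc,
        }

    if outdir is not None:
        _write_outputs(outdir, results, exclusion_log)
    return results


def _cv_train_scores(
    spec: riskmodel.ModelSpec,
    train_grid: pd.DataFrame,
    train_enc: pd.DataFrame,
    folds: int,
    seed: int,
) -> pd.DataFrame:
    """Cross-validated risk-score series over the training encounters.

    Encounters are split into stratified folds by outcome; each fold's full
    course is scored by a model fitted (with fresh balanced sampling) on the
    remaining folds.  Scores are out-of-fold for every training row.
    """
    from sklearn.model_selection import StratifiedKFold

    ids = train_enc["encounter_id"].to_numpy()
    y = train_enc["mv_flag"].astype(bool).to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    parts = []
    for f, (tr, te) in enumerate(skf.split(ids, y)):
        tr_ids = set(ids[tr])
        sub = train_grid[train_grid["encounter_id"].isin(tr_ids)]
        inst = riskmodel.sample_training_instances(sub, seed=seed + 100 + f)
        fold_spec = riskmodel.ModelSpec(
            model_id=spec.model_id, learner=spec.learner,
            params=spec.params, n_rounds=spec.n_rounds, seed=spec.seed + f,
        )
        m = riskmodel.fit(fold_spec, inst)
        held = train_grid[train_grid["encounter_id"].isin(set(ids[te]))]
        parts.append(riskmodel.score_series(m, held))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["encounter_id", "time"], kind="mergesort").reset_index(drop=True)


def _risk_group_stage(
    config, train_preds, train_series, test_series, train_enc, test_enc,
    policy, seeds,
) -> dict:
    full, full_ids, _pad, pad_ids = risk_groups.extract_trajectories(
        train_series, train_preds
    )
    if full.shape[0] < 3:
        raise ValueError("fewer than 3 full post-alert trajectories in training")
    # the KNN graph only carries cluster structure if neighborhoods are small
    # relative to the group sizes; n//4 matches the reference tuning at scale
    K = config.knn_K or min(200, max(10, full.shape[0] // 4))
    model = risk_groups.fit_risk_groups(
        full, K=K, k_max=config.k_max, k_nn=config.k_nn, seed=seeds[6]
    )
    stability = risk_groups.stability_jaccard(
        full, model.labels, K=K,
        n_boot=config.n_boot, seed=seeds[7],
    )
    test_preds = ew.encounter_predictions(test_series, policy)
    t_full, t_full_ids, t_pad, t_pad_ids = risk_groups.extract_trajectories(
        test_series, test_preds
    )
    test_rows = np.vstack([m for m in (t_full, t_pad) if m.size]) if (
        t_full.size or t_pad.size
    ) else np.empty((0, risk_groups.TRAJECTORY_POINTS))
    test_ids_all = list(t_full_ids) + list(t_pad_ids)
    labels = risk_groups.transfer_labels(model, test_rows)
    epps = dict(zip(test_preds["encounter_id"], test_preds["epp"]))
    table = risk_groups.group_metrics(labels, test_ids_all, test_enc, epps, model.k)
    return {
        "k": int(model.k),
        "train_n_clustered": int(full.shape[0]),
        "train_n_padded_excluded": len(pad_ids),
        "stability_jaccard": [float(x) for x in stability],
        "group_table": [
            {**row, "ewt_iqr_hours": list(row["ewt_iqr_hours"])}
            for row in table.to_dict(orient="records")
        ],
    }


def _manifest(config: RunConfig) -> dict:
    import sklearn
    import xgboost

    cfg = json.dumps(_config_dict(config), sort_keys=True)
    return {
        "config": _config_dict(config),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["filter"]["required_diagnosis_categories"] = sorted(
        d["filter"]["required_diagnosis_categories"]
    )
    d["models"] = list(d["models"])
    d["conv"]["filter_lengths"] = list(d["conv"]["filter_lengths"])
    for key in ("niv_prevalence_by_group",):
        d["generator"][key] = list(d["generator"][key])
    d["generator"]["los_lognormal_params"] = {
        k: list(v) for k, v in d["generator"]["los_lognormal_params"].items()
    }
    return d


def _write_outputs(outdir, results, exclusion_log) -> None:
    os.makedirs(outdir, exist_ok=True)
    public = {k: v for k, v in results.items() if not k.startswith("_")}
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(public, fh, indent=2, sort_keys=True, default=_json_default)
    exclusion_log.to_csv(os.path.join(outdir, "exclusion_log.csv"), index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
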
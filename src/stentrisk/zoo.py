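"""Six-model comparison behind one train/predict contract.

Logistic regression, SVM (Platt-calibrated probabilities), AdaBoost,
XGBoost, LightGBM, and the dual-stage AutoML framework. Comparators run
with library-default hyperparameters (only AutoML tunes itself, mirroring
the asymmetry of the study design) on the full standardized feature set.
Output is the familiar two-table layout: pooled out-of-fold
cross-validation metrics on the training cohort, and held-out metrics on
the test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .automl import AutoMLConfig, fit_automl, smote
from .metrics import full_report
from .preprocess import apply_preprocess, fit_preprocess
from .schema import CohortTable

MODEL_NAMES = ("LR", "SVM", "AdaBoost", "XGBoost", "LightGBM", "AutoML")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")


def _build(spec: ModelSpec, seed: int):
    hp = spec.hyperparams
    if spec.name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **hp)
    if spec.name == "SVM":
        return SVC(probability=True, random_state=seed, **hp)
    if spec.name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if spec.name == "XGBoost":
        return XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0, **hp
        )
    if spec.name == "LightGBM":
        return LGBMClassifier(
            random_state=seed, deterministic=True, force_row_wise=True,
            n_jobs=1, verbosity=-1, **hp
        )
    raise ValueError(spec.name)  # AutoML handled by the caller


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit a comparator on a standardized matrix; returns the fitted estimator."""
    est = _build(spec, seed)
    est.fit(X, y)
    return est


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def compare_models(
    train: CohortTable,
    test: CohortTable,
    specs: list[ModelSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    automl_config: AutoMLConfig | None = None,
    use_smote: bool = True,
    paper_mode: bool = False,
    threshold: float = 0.5,
    return_probs: bool = False,
):
    """Tables of CV (pooled out-of-fold) and held-out test metrics.

    ``paper_mode`` additionally oversamples the *evaluation* partitions to
    class parity before scoring — a protocol some studies use, never the
    default here because it inflates apparent prevalence.
    """
    specs = specs or [ModelSpec(n) for n in MODEL_NAMES]
    params = fit_preprocess(train)
    X_tr = apply_preprocess(params, train)
    X_te = apply_preprocess(params, test)
    y_tr, y_te = train.outcome, test.outcome

    cv_rows, test_rows, probs = {}, {}, {}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for spec in specs:
        if spec.name == "AutoML":
            cfg = automl_config or AutoMLConfig(seed=seed)
            fitted = fit_automl(train, cfg)
            p_oof = _automl_oof(train, cfg, skf)
            p_test = fitted.predict_proba(test)
            probs["AutoML_model"] = fitted
        else:
            p_oof = np.zeros(len(y_tr))
            for k, (tr, va) in enumerate(skf.split(X_tr, y_tr)):
                Xf, yf = X_tr[tr], y_tr[tr]
                if use_smote:
                    Xf, yf = smote(Xf, yf, seed=seed + k)
                model = train_model(spec, Xf, yf, seed=seed)
                p_oof[va] = predict_proba(model, X_tr[va])
            Xf, yf = (smote(X_tr, y_tr, seed=seed) if use_smote else (X_tr, y_tr))
            model = train_model(spec, Xf, yf, seed=seed)
            p_test = predict_proba(model, X_te)
        y_cv_eval, p_cv_eval = y_tr, p_oof
        y_te_eval, p_te_eval = y_te, p_test
        if paper_mode:
            y_cv_eval, p_cv_eval = _oversample_scores(y_tr, p_oof, seed)
            y_te_eval, p_te_eval = _oversample_scores(y_te, p_test, seed)
        cv_rows[spec.name] = full_report(y_cv_eval, p_cv_eval, threshold).as_dict()
        test_rows[spec.name] = full_report(y_te_eval, p_te_eval, threshold).as_dict()
        probs[spec.name] = {"oof": p_oof, "test": p_test}

    order = ["PRE", "SEN", "SPE", "ACC", "F1", "ROC-AUC", "PR-AUC"]
    cv_table = pd.DataFrame(cv_rows).T[order]
    test_table = pd.DataFrame(test_rows).T[order]
    if return_probs:
        return cv_table, test_table, probs
    return cv_table, test_table


def _automl_oof(train: CohortTable, cfg: AutoMLConfig, skf: StratifiedKFold) -> np.ndarray:
    y = train.outcome
    p = np.zeros(len(y))
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        sub_cfg = AutoMLConfig(
            plan=cfg.plan, hp_space=cfg.hp_space, hp_default=cfg.hp_default,
            stage1_pop=cfg.stage1_pop, stage1_iters=max(cfg.stage1_iters // 2, 2),
            stage2_pop=cfg.stage2_pop, stage2_iters=max(cfg.stage2_iters // 2, 2),
            smote_k=cfg.smote_k, seed=cfg.seed + 100 + k,
        )
        fitted = fit_automl(train.subset(tr), sub_cfg)
        p[va] = fitted.predict_proba(train.subset(va))
    return p


def _oversample_scores(y: np.ndarray, p: np.ndarray, seed: int):
    """Grow the minority of a scored evaluation set to parity by resampling
    (score-space analogue of oversampling the partition before scoring)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[int(np.argmin(counts))]
    n_new = int(counts.max() - counts.min())
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=n_new, replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return y[keep], p[keep]
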
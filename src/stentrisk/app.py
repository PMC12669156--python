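"""Risk scoring and the end-to-end pipeline behind the command line.

The single-patient scorer is the programmatic replacement for a bedside
decision app: given a fitted model and one validated patient record it
returns the occlusion probability on the 0-100% scale together with
per-feature Shapley contributions against the training background.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .automl import AutoMLConfig, CVPlan, FittedAutoML, Hyperparams, fit_automl
from .explain import (
    feature_overlap,
    lasso_logistic_path,
    shap_importance,
    shapley_values,
)
from .metrics import brier_and_calibration, dca_curve, pr_points, roc_points
from .preprocess import PreprocessParams, apply_preprocess
from .schema import CohortTable, load_cohort, save_cohort, schema_to_json
from .split import stratified_split
from .stats import baseline_frame, baseline_table
from .synth import default_spec, sample_cohort
from .zoo import compare_models

ARTIFACTS = (
    "baseline.csv",
    "metrics_cv.csv",
    "metrics_test.csv",
    "roc_pr_curves.csv",
    "dca_curve.csv",
    "calibration_curve.csv",
    "lasso_path.csv",
    "shap_values.csv",
    "manifest.json",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RiskReport:
    probability_pct: float  # 0-100 scale
    base_value: float  # background mean model output (probability scale)
    contributions: dict[str, float]  # per-feature Shapley, probability scale
    model_version: str
    inputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "probability_pct": self.probability_pct,
                "base_value": self.base_value,
                "contributions": self.contributions,
                "model_version": self.model_version,
                "inputs": {k: (v.item() if isinstance(v, np.generic) else v)
                           for k, v in self.inputs.items()},
            },
            indent=2,
        )


def predict_risk(
    model: FittedAutoML,
    patient: dict,
    background: CohortTable,
    nsamples: int = 10,
    seed: int = 0,
) -> RiskReport:
    """Score one patient; contributions sum (with the base) to the output.

    The patient record must supply every schema variable; missing names
    are reported together.
    """
    schema = background.schema
    missing = [v.name for v in schema if v.name not in patient]
    if missing:
        raise ValueError(f"missing required features: {missing}")
    row = pd.DataFrame([{v.name: patient[v.name] for v in schema}])
    single = CohortTable(schema, row, np.array([0]))
    prob = float(model.predict_proba(single)[0])

    Xe = apply_preprocess(model.preprocess, single)[:, model.feature_columns]
    Xb = apply_preprocess(model.preprocess, background)[:, model.feature_columns]
    names = [model.preprocess.feature_names[j] for j in model.feature_columns]
    S = shapley_values(
        model.predict_proba_matrix, Xe, Xb, nsamples=nsamples, seed=seed,
        method="exact" if len(names) <= 12 else "permutation",
        feature_names=names,
    )
    return RiskReport(
        probability_pct=100.0 * prob,
        base_value=float(S.base_value),
        contributions={n: float(v) for n, v in zip(names, S.values[0])},
        model_version=__version__,
        inputs=dict(patient),
    )


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: FittedAutoML, path: str | Path) -> None:
    payload = {
        "version": __version__,
        "mask_bits": list(model.mask.bits),
        "mask_origin": model.mask.origin,
        "hyperparams": model.hyperparams.__dict__,
        "preprocess": model.preprocess.to_dict(),
        "cv_score": model.cv_score,
        "feature_columns": model.feature_columns.tolist(),
        "booster": model.learner.booster_.model_to_string(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FittedAutoML:
    import lightgbm as lgb

    from .automl import FeatureMask

    payload = json.loads(Path(path).read_text())
    booster = lgb.Booster(model_str=payload["booster"])

    class _BoosterAdapter:
        """predict_proba facade over a bare LightGBM booster."""

        def __init__(self, b):
            self.booster_ = b

        def predict_proba(self, X):
            p = np.asarray(booster.predict(X))
            return np.column_stack([1.0 - p, p])

    return FittedAutoML(
        mask=FeatureMask(tuple(bool(b) for b in payload["mask_bits"]),
                         payload.get("mask_origin", "automl")),
        hyperparams=Hyperparams(**payload["hyperparams"]),
        preprocess=PreprocessParams.from_dict(payload["preprocess"]),
        learner=_BoosterAdapter(booster),
        cv_score=float(payload["cv_score"]),
        feature_columns=np.asarray(payload["feature_columns"], dtype=int),
        config=AutoMLConfig(),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 20250826,
    "n": 826,
    "train_fraction": 0.8,
    "cohort_csv": None,  # load instead of simulate when set
    "folds": 5,
    "stage1_pop": 8,
    "stage1_iters": 10,
    "stage2_pop": 8,
    "stage2_iters": 10,
    "models": ["LR", "SVM", "AdaBoost", "XGBoost", "LightGBM", "AutoML"],
    "shap_samples": 40,
    "shap_background": 50,
    "shap_permutations": 10,
    "lasso_lambdas": 60,
    "plots": False,
    "output_dir": "stentrisk_run",
}


def run_pipeline(config: dict | None = None) -> dict:
    """Simulate/load -> split -> fit & compare -> evaluate -> explain -> report.

    Writes the declared artifact set to ``output_dir`` and returns a summary
    dict. Any stage failure aborts with the stage name and cause.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error path
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("data")
    def table() -> CohortTable:
        if cfg["cohort_csv"]:
            return load_cohort(cfg["cohort_csv"], default_spec().schema)
        return sample_cohort(default_spec(), int(cfg["n"]), seed)

    @stage("split")
    def parts():
        split = stratified_split(table, float(cfg["train_fraction"]), seed)
        return split, table.subset(split.train_array()), table.subset(split.test_array())

    split, train, test = parts

    @stage("baseline")
    def _baseline():
        df = baseline_frame(baseline_table(table, split))
        df.to_csv(out / "baseline.csv", index=False)
        return df

    @stage("models")
    def model_results():
        automl_cfg = AutoMLConfig(
            plan=CVPlan(folds=int(cfg["folds"]), seed=seed),
            stage1_pop=int(cfg["stage1_pop"]), stage1_iters=int(cfg["stage1_iters"]),
            stage2_pop=int(cfg["stage2_pop"]), stage2_iters=int(cfg["stage2_iters"]),
            seed=seed,
        )
        from .zoo import ModelSpec

        specs = [ModelSpec(n) for n in cfg["models"]]
        if "AutoML" not in cfg["models"]:
            specs.append(ModelSpec("AutoML"))
        cv_tab, test_tab, probs = compare_models(
            train, test, specs, folds=int(cfg["folds"]), seed=seed,
            automl_config=automl_cfg, return_probs=True,
        )
        cv_tab.to_csv(out / "metrics_cv.csv")
        test_tab.to_csv(out / "metrics_test.csv")
        return cv_tab, test_tab, probs

    cv_tab, test_tab, probs = model_results
    fitted: FittedAutoML = probs["AutoML_model"]
    p_test = probs["AutoML"]["test"]
    y_test = test.outcome

    @stage("evaluate")
    def _curves():
        roc = roc_points(y_test, p_test).assign(curve="roc")
        pr = pr_points(y_test, p_test).assign(curve="pr")
        pd.concat([roc, pr]).to_csv(out / "roc_pr_curves.csv", index=False)
        dca_curve(y_test, p_test).frame().to_csv(out / "dca_curve.csv", index=False)
        cal = brier_and_calibration(y_test, p_test)
        pd.DataFrame(
            {"mean_predicted": cal.mean_predicted, "observed_fraction": cal.observed_fraction}
        ).to_csv(out / "calibration_curve.csv", index=False)
        return cal

    cal = _curves

    @stage("explain")
    def explain_results():
        from .preprocess import fit_preprocess

        params = fit_preprocess(train)
        X = apply_preprocess(params, train)
        path = lasso_logistic_path(
            X, train.outcome, n_lambdas=int(cfg["lasso_lambdas"]), seed=seed,
            feature_names=params.feature_names,
        )
        rows = pd.DataFrame(path.coefs, index=path.feature_names, columns=path.lambdas)
        rows.to_csv(out / "lasso_path.csv")
        lasso_vars = sorted({n.split("=")[0] for n in path.selected})
        automl_vars = fitted.selected_features()
        frac, inter = (feature_overlap(set(lasso_vars), set(automl_vars))
                       if lasso_vars else (float("nan"), set()))

        rng = np.random.default_rng(seed)
        nb = min(int(cfg["shap_background"]), len(train))
        ne = min(int(cfg["shap_samples"]), len(test))
        Xb = apply_preprocess(fitted.preprocess, train)[:, fitted.feature_columns]
        Xb = Xb[rng.choice(len(Xb), nb, replace=False)]
        Xe = apply_preprocess(fitted.preprocess, test)[:, fitted.feature_columns][:ne]
        names = [fitted.preprocess.feature_names[j] for j in fitted.feature_columns]
        S = shapley_values(
            fitted.predict_proba_matrix, Xe, Xb,
            nsamples=int(cfg["shap_permutations"]), seed=seed,
            method="permutation", feature_names=names,
        )
        pd.DataFrame(S.values, columns=names).to_csv(out / "shap_values.csv", index=False)
        importance = shap_importance(S)
        return lasso_vars, automl_vars, frac, importance

    lasso_vars, automl_vars, overlap_frac, importance = explain_results

    @stage("report")
    def _manifest():
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config": {k: v for k, v in cfg.items()},
            "seed": seed,
            "n_train": len(train),
            "n_test": len(test),
            "automl_selected": automl_vars,
            "automl_hyperparams": fitted.hyperparams.__dict__,
            "automl_cv_score": fitted.cv_score,
            "lasso_selected": lasso_vars,
            "overlap_fraction": overlap_frac,
            "test_brier": cal.brier,
            "shap_importance": importance.to_dict(orient="records"),
            "metrics_test": test_tab.round(4).to_dict(orient="index"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    if cfg.get("plots"):
        _render_plots(out, y_test, p_test)

    summary.update(_manifest)
    return summary


def _render_plots(out: Path, y, p) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    roc = roc_points(y, p)
    axes[0, 0].plot(roc.fpr, roc.tpr)
    axes[0, 0].plot([0, 1], [0, 1], "k--")
    axes[0, 0].set_title("ROC")
    pr = pr_points(y, p)
    axes[0, 1].plot(pr.recall, pr.precision)
    axes[0, 1].set_title("Precision-Recall")
    nb = dca_curve(y, p)
    axes[1, 0].plot(nb.thresholds, nb.nb_model, label="model")
    axes[1, 0].plot(nb.thresholds, nb.nb_all, label="treat all")
    axes[1, 0].axhline(0, color="k", lw=0.8, label="treat none")
    axes[1, 0].set_ylim(-0.1, None)
    axes[1, 0].legend()
    axes[1, 0].set_title("Decision curve")
    cal = brier_and_calibration(y, p)
    axes[1, 1].plot(cal.mean_predicted, cal.observed_fraction, "o-")
    axes[1, 1].plot([0, 1], [0, 1], "k--")
    axes[1, 1].set_title(f"Calibration (Brier {cal.brier:.3f})")
    fig.tight_layout()
    fig.savefig(out / "performance.png", dpi=120)
    plt.close(fig)


def simulate_to_csv(n: int, seed: int, csv_path: str | Path, schema_path: str | Path | None = None):
    spec = default_spec()
    table = sample_cohort(spec, n, seed)
    save_cohort(table, csv_path)
    if schema_path:
        schema_to_json(spec.schema, schema_path)
    return table
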
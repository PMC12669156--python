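"""Dual-stage AutoML driven by the sequoia optimizer.

Stage 1 screens a discrete feature mask (one bit per predictor variable,
continuous optimizer positions squashed through a sigmoid transfer
function); stage 2 tunes the gradient-boosted-tree hyperparameters in
their continuous box, conditioned on the stage-1 mask. Fitness for both
stages is mean out-of-fold ROC-AUC under stratified five-fold
cross-validation, minus a small parsimony penalty, with standardization
and SMOTE re-fitted strictly inside each fold-training partition so no
information leaks from validation rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

# lightgbm's sklearn wrapper invents placeholder feature names for ndarray
# inputs and sklearn then complains at predict time; harmless interop noise
warnings.filterwarnings("ignore", message="X does not have valid feature names")

from .metrics import roc_auc
from .optim import OptimizerConfig, SearchSpace, iseq_optimize
from .preprocess import PreprocessParams, apply_preprocess, fit_preprocess
from .schema import CohortTable

PARSIMONY_PENALTY = 0.01


@dataclass(frozen=True)
class FeatureMask:
    bits: tuple[bool, ...]
    origin: str = "automl"  # automl | lasso | manual

    def __post_init__(self) -> None:
        if not any(self.bits):
            raise ValueError("a feature mask used for fitting needs at least one bit set")

    @property
    def n_selected(self) -> int:
        return int(sum(self.bits))

    def selected_names(self, names) -> list[str]:
        return [n for n, b in zip(names, self.bits) if b]


@dataclass(frozen=True)
class HyperparamSpace:
    """Boxes for the boosted-tree learner; integers are rounded at evaluation."""

    n_estimators: tuple[int, int] = (50, 500)
    max_depth: tuple[int, int] = (2, 8)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    subsample: tuple[float, float] = (0.5, 1.0)
    min_child_samples: tuple[int, int] = (1, 20)
    reg_lambda: tuple[float, float] = (0.0, 10.0)

    _INT = ("n_estimators", "max_depth", "min_child_samples")

    def names(self) -> list[str]:
        return ["n_estimators", "max_depth", "learning_rate", "subsample",
                "min_child_samples", "reg_lambda"]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self, n)[0] for n in self.names()], dtype=float)
        hi = np.array([getattr(self, n)[1] for n in self.names()], dtype=float)
        return lo, hi

    def decode(self, position: np.ndarray) -> "Hyperparams":
        lo, hi = self.bounds()
        x = np.clip(position, lo, hi)
        vals = {}
        for j, n in enumerate(self.names()):
            vals[n] = int(round(x[j])) if n in self._INT else float(x[j])
        return Hyperparams(**vals)

    def encode(self, hp: "Hyperparams") -> np.ndarray:
        return np.array([getattr(hp, n) for n in self.names()], dtype=float)

    def contains(self, hp: "Hyperparams") -> bool:
        lo, hi = self.bounds()
        x = self.encode(hp)
        return bool(np.all(x >= lo) and np.all(x <= hi))


@dataclass(frozen=True)
class Hyperparams:
    n_estimators: int = 150
    max_depth: int = 4
    learning_rate: float = 0.1
    subsample: float = 0.9
    min_child_samples: int = 5
    reg_lambda: float = 1.0


@dataclass(frozen=True)
class CVPlan:
    folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class AutoMLConfig:
    plan: CVPlan = CVPlan()
    hp_space: HyperparamSpace = HyperparamSpace()
    hp_default: Hyperparams = Hyperparams()
    stage1_pop: int = 10
    stage1_iters: int = 15
    stage2_pop: int = 10
    stage2_iters: int = 15
    smote_k: int = 5
    paper_mode: bool = False  # oversample evaluation partitions too (not default)
    seed: int = 0


def _make_learner(hp: Hyperparams, seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        num_leaves=min(2**hp.max_depth, 64),
        learning_rate=hp.learning_rate,
        subsample=hp.subsample,
        subsample_freq=1 if hp.subsample < 1.0 else 0,
        min_child_samples=hp.min_child_samples,
        reg_lambda=hp.reg_lambda,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )


def mask_from_position(position: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """Sigmoid transfer: bit_i = 1 iff u_i < S(x_i); an all-zero draw is
    rescued by setting the bit with the largest activation."""
    x = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")
    s = 1.0 / (1.0 + np.exp(-x))
    bits = rng.uniform(size=len(x)) < s
    if not bits.any():
        bits[int(np.argmax(s))] = True
    return FeatureMask(tuple(bool(b) for b in bits))


def smote(
    X: np.ndarray, y: np.ndarray, k: int = 5, target_minority: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Each synthetic point is ``x_i + u (x_nn - x_i)`` with u ~ U(0, 1) and
    ``x_nn`` one of the k nearest minority neighbours of a random minority
    sample ``x_i``. Originals are retained; the minority class is grown to
    ``target_minority`` (default: parity with the majority).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects a binary outcome")
    minority = classes[int(np.argmin(counts))]
    n_min = int(counts.min())
    if target_minority is None:
        target_minority = int(counts.max())
    n_new = target_minority - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    if n_min <= k:
        raise ValueError(
            f"minority count {n_min} must exceed k={k}; reduce k or pool more data"
        )
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    parents = rng.integers(n_min, size=n_new)
    picks = neigh[parents, rng.integers(k, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    synth = Xm[parents] + u * (Xm[picks] - Xm[parents])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


def _mask_columns(params: PreprocessParams, mask: FeatureMask) -> np.ndarray:
    """Design-matrix column indices selected by a variable-level mask."""
    keep = {v for v, b in zip(params.source_columns, mask.bits) if b}
    idx = [
        j for j, name in enumerate(params.feature_names)
        if (name.split("=")[0] if "=" in name else name) in keep
    ]
    return np.array(idx, dtype=int)


def cv_fitness(
    table: CohortTable,
    mask: FeatureMask,
    hp: Hyperparams,
    plan: CVPlan,
    smote_k: int = 5,
    audit: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> float:
    """Mean out-of-fold ROC-AUC minus a parsimony penalty.

    Standardization and SMOTE are fitted on the fold-training rows only;
    the optional ``audit`` callback receives (fold, fit_rows, val_rows) for
    leakage checks.
    """
    if len(mask.bits) != len(table.schema):
        raise ValueError("mask length must equal the number of predictors")
    y = table.outcome
    skf = StratifiedKFold(n_splits=plan.folds, shuffle=True, random_state=plan.seed)
    aucs = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        if audit is not None:
            audit(fold, tr, va)
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold lost one outcome class; use stratified folds")
        sub_tr = table.subset(tr)
        params = fit_preprocess(sub_tr)
        cols = _mask_columns(params, mask)
        X_tr = apply_preprocess(params, sub_tr)[:, cols]
        X_va = apply_preprocess(params, table.subset(va))[:, cols]
        X_bal, y_bal = smote(X_tr, y[tr], k=smote_k, seed=plan.seed + 1000 + fold)
        learner = _make_learner(hp, seed=plan.seed + fold)
        learner.fit(X_bal, y_bal)
        p = learner.predict_proba(X_va)[:, 1]
        aucs.append(roc_auc(y[va], p))
    penalty = PARSIMONY_PENALTY * mask.n_selected / len(mask.bits)
    return float(np.mean(aucs)) - penalty


class _FitnessCache:
    """Memoizes cv_fitness per decoded decision (mask bits or hyperparams)."""

    def __init__(self, fn):
        self.fn = fn
        self.store: dict = {}
        self.calls = 0

    def __call__(self, key, *args):
        if key not in self.store:
            self.store[key] = self.fn(*args)
            self.calls += 1
        return self.store[key]


def stage1_select(
    table: CohortTable, hp0: Hyperparams, plan: CVPlan, config: AutoMLConfig,
    record_trace: list | None = None,
) -> tuple[FeatureMask, float]:
    """Screen the discrete feature space; returns (best mask, its fitness).

    ``record_trace`` (optional) collects the best-so-far fitness after each
    mask evaluation, for budget-monotonicity audits.
    """
    p = len(table.schema)
    if p == 1:
        mask = FeatureMask((True,))
        return mask, cv_fitness(table, mask, hp0, plan, config.smote_k)
    transfer_rng = np.random.default_rng(config.seed + 17)
    cache = _FitnessCache(lambda m: cv_fitness(table, m, hp0, plan, config.smote_k))
    best: dict = {"mask": None, "fit": -np.inf}

    def objective(position):
        mask = mask_from_position(position, transfer_rng)
        fit = cache(mask.bits, mask)
        if fit > best["fit"]:
            best["fit"], best["mask"] = fit, mask
        if record_trace is not None:
            record_trace.append(best["fit"])
        return -fit

    space = SearchSpace(p, np.full(p, -4.0), np.full(p, 4.0), discrete=True)
    opt_cfg = OptimizerConfig(
        pop_size=config.stage1_pop, max_iters=config.stage1_iters, seed=config.seed
    )
    # seed the all-features mask so a variable is only dropped when doing so
    # actually scores better than keeping everything
    full = FeatureMask((True,) * p)
    fit_full = cache(full.bits, full)
    if fit_full > best["fit"]:
        best["fit"], best["mask"] = fit_full, full
    iseq_optimize(objective, space, opt_cfg)
    # guard against the winner's curse of noisy CV fitness: re-score the top
    # candidates under a second fold split and pick by the averaged score
    top = sorted(cache.store.items(), key=lambda kv: -kv[1])[:4]
    replan = CVPlan(plan.folds, plan.stratified, plan.seed + 7717)
    rescored = [
        (bits, 0.5 * (fit + cv_fitness(table, FeatureMask(bits), hp0, replan, config.smote_k)))
        for bits, fit in top
    ]
    bits, fit = max(rescored, key=lambda kv: kv[1])
    return FeatureMask(bits), float(fit)


def stage2_tune(
    table: CohortTable, mask: FeatureMask, space: HyperparamSpace, plan: CVPlan,
    config: AutoMLConfig,
) -> tuple[Hyperparams, float]:
    """Tune the learner box conditioned on the stage-1 mask."""
    cache = _FitnessCache(lambda hp: cv_fitness(table, mask, hp, plan, config.smote_k))
    best: dict = {"hp": config.hp_default, "fit": -np.inf}

    def objective(position):
        hp = space.decode(position)
        fit = cache(hp, hp)
        if fit > best["fit"]:
            best["fit"], best["hp"] = fit, hp
        return -fit

    lo, hi = space.bounds()
    opt_space = SearchSpace(len(lo), lo, hi)
    opt_cfg = OptimizerConfig(
        pop_size=config.stage2_pop, max_iters=config.stage2_iters, seed=config.seed + 1
    )
    # seed the default point so tuning can never end worse than the default
    objective(space.encode(config.hp_default))
    iseq_optimize(objective, opt_space, opt_cfg)
    return best["hp"], float(best["fit"])


@dataclass
class FittedAutoML:
    mask: FeatureMask
    hyperparams: Hyperparams
    preprocess: PreprocessParams
    learner: LGBMClassifier
    cv_score: float
    feature_columns: np.ndarray
    config: AutoMLConfig

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        X = apply_preprocess(self.preprocess, table)[:, self.feature_columns]
        return self.learner.predict_proba(X)[:, 1]

    def predict_proba_matrix(self, X_encoded: np.ndarray) -> np.ndarray:
        """Probabilities from an already-encoded, already-masked matrix."""
        return self.learner.predict_proba(X_encoded)[:, 1]

    def selected_features(self) -> list[str]:
        return self.mask.selected_names(self.preprocess.source_columns)


def fit_automl(table: CohortTable, config: AutoMLConfig | None = None) -> FittedAutoML:
    """Stage 1 -> stage 2 -> final refit on the rebalanced training table."""
    config = config or AutoMLConfig()
    plan = replace(config.plan, seed=config.plan.seed or config.seed)
    mask, fit1 = stage1_select(table, config.hp_default, plan, config)
    hp, fit2 = stage2_tune(table, mask, config.hp_space, plan, config)
    params = fit_preprocess(table)
    cols = _mask_columns(params, mask)
    X = apply_preprocess(params, table)[:, cols]
    X_bal, y_bal = smote(X, table.outcome, k=config.smote_k, seed=config.seed + 5)
    learner = _make_learner(hp, seed=config.seed)
    learner.fit(X_bal, y_bal)
    return FittedAutoML(mask, hp, params, learner, max(fit1, fit2), cols, config)
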
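"""Interpretability layer: LASSO validation, Shapley attribution, interactions.

The screening story is: the AutoML mask proposes a feature subset, an
L1-penalized logistic path (with cross-validated deviance and the
one-standard-error rule) independently validates it, the overlap between
the two lists is quantified, and Shapley values explain the fitted model
sample by sample.

Shapley values are computed against a background dataset: the value of a
coalition S is the mean model output with the features in S taken from the
explained sample and the rest from background rows. Small problems
(d <= 16) are solved by exact subset enumeration; larger ones by
permutation sampling with antithetic pairs, which preserves exact local
accuracy (the per-permutation contributions telescope to
``f(x) - base``) while the per-feature Monte-Carlo error shrinks as
1/sqrt(n_permutations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression


# ---------------------------------------------------------------------------
# LASSO path
# ---------------------------------------------------------------------------

@dataclass
class LassoPath:
    lambdas: np.ndarray  # decreasing grid
    coefs: np.ndarray  # (n_features, n_lambdas)
    intercepts: np.ndarray
    cv_deviance: np.ndarray  # mean per lambda
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected: list[str]  # nonzero features at lambda_1se
    feature_names: list[str] = field(default_factory=list)
    converged: np.ndarray | None = None

    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coefs) > 1e-10).sum(axis=0)


def _l1_fit(X, y, lam, warm=None):
    n = len(y)
    # sklearn's objective is ||w||_1 + C * sum(logloss); C = 1/(n*lambda)
    # makes lambda the per-sample penalty used in the KKT conditions.
    model = LogisticRegression(
        penalty="l1", C=1.0 / (n * lam), solver="saga", max_iter=8000,
        tol=1e-7, warm_start=False, random_state=0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model.fit(X, y)
        converged = not any("onverge" in str(w.message) for w in caught)
    return model.coef_.ravel().copy(), float(model.intercept_[0]), converged


def _binomial_deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
    lambda_ratio: float = 1e-4,
    cv_folds: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> LassoPath:
    """L1 logistic path with CV deviance and the 1-SE selection rule.

    ``lambda_1se`` is the largest penalty whose mean CV deviance is within
    one standard error of the minimum; the selected set is the support of
    the full-data solution there. Non-converged solutions are flagged and
    the path continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if lambdas is None:
        ybar = y.mean()
        # small headroom over the exact null-model threshold so the all-zero
        # solution is strictly optimal at the top of the grid
        lam_max = 1.001 * np.abs(X.T @ (y - ybar)).max() / n
        lambdas = np.geomspace(lam_max, lam_max * lambda_ratio, n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)

    coefs = np.zeros((p, len(lambdas)))
    intercepts = np.zeros(len(lambdas))
    converged = np.ones(len(lambdas), dtype=bool)
    for i, lam in enumerate(lambdas):
        coefs[:, i], intercepts[i], ok = _l1_fit(X, y, lam)
        if not ok:
            converged[i] = False
            warnings.warn(f"L1 path did not converge at lambda={lam:.3g}")

    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    dev = np.zeros((cv_folds, len(lambdas)))
    for k, (tr, va) in enumerate(skf.split(X, y)):
        for i, lam in enumerate(lambdas):
            w, b, _ = _l1_fit(X[tr], y[tr], lam)
            eta = X[va] @ w + b
            dev[k, i] = _binomial_deviance(y[va], 1.0 / (1.0 + np.exp(-eta)))
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / math.sqrt(cv_folds)

    i_min = int(np.argmin(cv_mean))
    thresh = cv_mean[i_min] + cv_se[i_min]
    ok_idx = np.flatnonzero(cv_mean <= thresh)
    i_1se = int(ok_idx[np.argmax(lambdas[ok_idx])])
    names = feature_names or [f"x{j}" for j in range(p)]
    selected = [names[j] for j in np.flatnonzero(np.abs(coefs[:, i_1se]) > 1e-10)]
    return LassoPath(
        lambdas, coefs, intercepts, cv_mean, cv_se,
        float(lambdas[i_min]), float(lambdas[i_1se]), selected, names, converged,
    )


def feature_overlap(reference: set, candidate: set) -> tuple[float, set]:
    """Overlap fraction |reference & candidate| / |reference| (percent /100)."""
    reference, candidate = set(reference), set(candidate)
    if not reference:
        raise ValueError("reference feature set must be non-empty")
    inter = reference & candidate
    return len(inter) / len(reference), inter


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

@dataclass
class ShapMatrix:
    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    model_output: np.ndarray  # (n_samples,)
    se: np.ndarray | None = None  # Monte-Carlo SEs (sampled method only)
    feature_names: list[str] = field(default_factory=list)

    def local_accuracy_gap(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1) - self.model_output


def _model_fn(model):
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    return lambda X: model.predict_proba(np.asarray(X))[:, 1]


def shapley_values(
    model,
    X_explain: np.ndarray,
    X_background: np.ndarray,
    nsamples: int = 20,
    seed: int = 0,
    method: str = "auto",
    feature_names: list[str] | None = None,
) -> ShapMatrix:
    """Background-conditional Shapley attribution of the model output.

    ``method='exact'`` enumerates all 2^d coalitions (d <= 16);
    ``'permutation'`` averages marginal contributions over ``nsamples``
    random permutations in antithetic (forward/reverse) pairs.
    """
    f = _model_fn(model)
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    if len(Xb) == 0:
        raise ValueError("background must be non-empty")
    nx, d = Xe.shape
    if method == "auto":
        method = "exact" if d <= 12 else "permutation"
    base = float(np.mean(f(Xb)))
    outputs = np.asarray(f(Xe), dtype=float)
    names = feature_names or [f"x{j}" for j in range(d)]

    if method == "exact":
        if d > 16:
            raise ValueError("exact enumeration is limited to d <= 16")
        phi = _shap_exact(f, Xe, Xb, base, outputs)
        return ShapMatrix(phi, base, outputs, None, names)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if nsamples < 2:
        raise ValueError("the sampled method needs nsamples >= 2")
    phi, se = _shap_permutation(f, Xe, Xb, nsamples, seed)
    return ShapMatrix(phi, base, outputs, se, names)


def _shap_exact(f, Xe, Xb, base, outputs):
    nx, d = Xe.shape
    nb = len(Xb)
    nsub = 1 << d
    # v[s, i]: coalition value of subset bitmask s for explained sample i
    v = np.empty((nsub, nx))
    v[0] = base
    v[nsub - 1] = outputs
    for s in range(1, nsub - 1):
        members = [j for j in range(d) if s >> j & 1]
        Z = np.repeat(Xb[None, :, :], nx, axis=0)  # (nx, nb, d)
        Z[:, :, members] = Xe[:, None, members]
        v[s] = f(Z.reshape(nx * nb, d)).reshape(nx, nb).mean(axis=1)
    # Shapley weights w(|S|) for S not containing j
    fact = [math.factorial(k) for k in range(d + 1)]
    w = np.array([fact[k] * fact[d - k - 1] / fact[d] for k in range(d)])
    phi = np.zeros((nx, d))
    for s in range(nsub):
        k = bin(s).count("1")
        if k == d:
            continue
        for j in range(d):
            if not s >> j & 1:
                phi[:, j] += w[k] * (v[s | 1 << j] - v[s])
    return phi


def _shap_permutation(f, Xe, Xb, nsamples, seed):
    nx, d = Xe.shape
    nb = len(Xb)
    rng = np.random.default_rng(seed)
    n_pairs = max(nsamples // 2, 1)
    perms = []
    for _ in range(n_pairs):
        p = rng.permutation(d)
        perms.append(p)
        perms.append(p[::-1])  # antithetic partner
    contrib = np.zeros((len(perms), nx, d))
    base = np.mean(f(Xb))
    for m, perm in enumerate(perms):
        # chain of d coalition values per explained sample, evaluated in one call
        Z = np.repeat(Xb[None, :, :], nx * d, axis=0).reshape(nx, d, nb, d)
        for step in range(d):
            cols = perm[: step + 1]
            Z[:, step][:, :, cols] = Xe[:, None, cols]
        vals = f(Z.reshape(nx * d * nb, d)).reshape(nx, d, nb).mean(axis=2)
        prev = np.full(nx, base)
        for step, j in enumerate(perm):
            contrib[m, :, j] = vals[:, step] - prev
            prev = vals[:, step]
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / math.sqrt(len(perms))
    return phi, se


def shap_importance(S: ShapMatrix) -> pd.DataFrame:
    """Features ranked by mean |phi| (ties broken alphabetically)."""
    if S.values.size == 0:
        raise ValueError("empty attribution matrix")
    imp = np.abs(S.values).mean(axis=0)
    df = pd.DataFrame({"feature": S.feature_names, "mean_abs_shap": imp})
    return df.sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# interaction summaries
# ---------------------------------------------------------------------------

@dataclass
class InteractionSummary:
    pair: tuple[str, str]
    thresholds: tuple[float, float]
    quadrant_mean: dict  # ("high","high") etc. -> mean contribution or None
    quadrant_count: dict
    synergy_score: float  # hh - hl - lh + ll excess
    synergy_se: float


def interaction_summary(
    S: ShapMatrix, X: np.ndarray, pair: tuple[str, str], thresholds: tuple[float, float]
) -> InteractionSummary:
    """Quadrant analysis of a feature pair's joint Shapley contribution.

    Samples are partitioned by each feature being above ("high") or below
    its threshold; the summary reports the mean of phi_a + phi_b per
    quadrant and the interaction excess

        synergy = m(high,high) - m(high,low) - m(low,high) + m(low,low),

    which is ~0 for an additive model. Empty quadrants are reported as
    absent (mean None) and make the score undefined (NaN).
    """
    a, b = (S.feature_names.index(p) for p in pair)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    contrib = S.values[:, a] + S.values[:, b]
    hi_a = X[:, a] > thresholds[0]
    hi_b = X[:, b] > thresholds[1]
    means, counts, variances = {}, {}, {}
    for ka, ma in (("high", hi_a), ("low", ~hi_a)):
        for kb, mb in (("high", hi_b), ("low", ~hi_b)):
            m = ma & mb
            counts[(ka, kb)] = int(m.sum())
            means[(ka, kb)] = float(contrib[m].mean()) if m.any() else None
            variances[(ka, kb)] = float(contrib[m].var(ddof=1)) if m.sum() > 1 else np.nan
    if any(v is None for v in means.values()):
        score, se = float("nan"), float("nan")
    else:
        score = (means[("high", "high")] - means[("high", "low")]
                 - means[("low", "high")] + means[("low", "low")])
        se = math.sqrt(sum(
            (0.0 if np.isnan(variances[q]) else variances[q]) / max(counts[q], 1)
            for q in counts
        ))
    return InteractionSummary(tuple(pair), tuple(thresholds), means, counts, score, se)


def interaction_probe(
    model,
    X: np.ndarray,
    feature_names: list[str],
    pair: tuple[str, str],
    thresholds: tuple[float, float],
    per_quadrant: int = 35,
    nsamples: int = 8,
    n_background: int = 40,
    seed: int = 0,
) -> InteractionSummary:
    """End-to-end synergy detector for one feature pair.

    Explained samples are drawn quadrant-balanced (up to ``per_quadrant``
    from each threshold quadrant) so the sparse high/high cell is estimated
    with comparable precision to the others, then attributed with sampled
    Shapley values and summarized by :func:`interaction_summary`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    a, b = (feature_names.index(p) for p in pair)
    hi_a = X[:, a] > thresholds[0]
    hi_b = X[:, b] > thresholds[1]
    sel: list[int] = []
    for ma in (hi_a, ~hi_a):
        for mb in (hi_b, ~hi_b):
            idx = np.flatnonzero(ma & mb)
            if len(idx):
                sel.extend(rng.choice(idx, min(len(idx), per_quadrant), replace=False))
    sel_arr = np.asarray(sel)
    Xb = X[rng.choice(len(X), min(n_background, len(X)), replace=False)]
    S = shapley_values(
        model, X[sel_arr], Xb, nsamples=nsamples, seed=seed,
        method="permutation", feature_names=feature_names,
    )
    return interaction_summary(S, X[sel_arr], pair, thresholds)
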
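"""Feature attribution: model-specific importances and exact Shapley values.

With only five descriptors, Shapley values are computed by exact
enumeration of all 2^5 coalitions under the interventional (marginal) value
function: the value of a coalition S is the mean model output over a fixed
background sample with the features in S replaced by the explained frame's
values. Exactness removes the approximation nondeterminism of sampling
estimators; a fixed seeded background keeps results reproducible.

For probabilistic classifiers attributions default to the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import bootstrap_ci

__all__ = [
    "model_importance",
    "exact_shapley",
    "shapley_matrix",
    "global_shap_summary",
    "log_odds_fn",
    "sample_background",
]


def _final_estimator(model):
    return model.steps[-1][1] if hasattr(model, "steps") else model


def model_importance(model) -> np.ndarray:
    """Model-specific importances: |standardized coefficient| for logistic
    regression, normalized impurity share (summing to 1) for tree ensembles."""
    est = _final_estimator(model)
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_).ravel())
    if hasattr(est, "feature_importances_"):
        imp = np.asarray(est.feature_importances_, dtype=float)
        total = imp.sum()
        return imp / total if total > 0 else imp
    raise TypeError(f"unsupported model type {type(est).__name__}: "
                    "expected coefficients or impurity importances")


def log_odds_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap a probabilistic classifier as a log-odds scoring function."""
    def fn(X: np.ndarray) -> np.ndarray:
        p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        return np.log(p / (1.0 - p))
    return fn


def sample_background(X: np.ndarray, size: int = 256, rng_seed: int = 0) -> np.ndarray:
    """Fixed, seeded background sample of training frames."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(rng_seed)
    if len(X) <= size:
        return X.copy()
    return X[rng.choice(len(X), size=size, replace=False)]


def exact_shapley(predict_fn: Callable[[np.ndarray], np.ndarray],
                  x: np.ndarray, background: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for one frame.

    Returns (phi, baseline) with baseline = v(empty set), the mean model
    output on the background. Efficiency holds by construction:
    sum(phi) = f(x) - baseline.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or len(background) == 0:
        raise ValueError("background must be a non-empty 2-D sample")
    d = len(x)
    values: dict[frozenset, float] = {}
    for r in range(d + 1):
        for S in combinations(range(d), r):
            X_eval = background.copy()
            if S:
                X_eval[:, list(S)] = x[list(S)]
            out = predict_fn(X_eval)
            if not np.all(np.isfinite(out)):
                raise ValueError("predict_fn returned non-finite values")
            values[frozenset(S)] = float(np.mean(out))
    phi = np.zeros(d)
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for r in range(d):
            w = factorial(r) * factorial(d - r - 1) / factorial(d)
            for S in combinations(others, r):
                fs = frozenset(S)
                phi[i] += w * (values[fs | {i}] - values[fs])
    return phi, values[frozenset()]


def shapley_matrix(predict_fn: Callable[[np.ndarray], np.ndarray],
                   X_explain: np.ndarray, background: np.ndarray
                   ) -> tuple[np.ndarray, float]:
    """Per-frame Shapley values for many frames (rows of X_explain)."""
    X_explain = np.asarray(X_explain, dtype=float)
    phis = np.empty_like(X_explain)
    baseline = 0.0
    for i, x in enumerate(X_explain):
        phis[i], baseline = exact_shapley(predict_fn, x, background)
    return phis, baseline


def global_shap_summary(phi_matrix: np.ndarray,
                        feature_names: Sequence[str],
                        rng_seed: int = 0, n_bootstrap: int = 2000
                        ) -> pd.DataFrame:
    """Global summary: per-feature mean |phi| with percentile bootstrap CIs
    over frames. Single-frame input yields zero-width intervals."""
    phi = np.asarray(phi_matrix, dtype=float)
    if phi.ndim != 2 or len(phi) == 0:
        raise ValueError("phi_matrix must be a non-empty (frames, features) array")
    absphi = np.abs(phi)
    rows = []
    for j, name in enumerate(feature_names):
        mean = float(absphi[:, j].mean())
        if len(phi) == 1 or np.ptp(absphi[:, j]) == 0:
            lo = hi = mean
        else:
            df = pd.DataFrame({"v": absphi[:, j]})
            lo, hi = bootstrap_ci(lambda d: float(d["v"].mean()), df,
                                  n_replicates=n_bootstrap, rng_seed=rng_seed)
        rows.append({"feature": name, "mean_abs_shap": mean,
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
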
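"""Frame-level pathogenicity classification under leave-one-mutation-out CV.

Each fold holds out every conformer of one variant (WT counts as a variant
for splitting but is always part of some training set in other folds).
Features are re-standardized per fold from training-fold statistics only.
AUROC is computed on pooled out-of-fold predictions — never per fold, since
single-class held-out variants make per-fold AUROC undefined. Confidence
intervals use percentile bootstrap (2000 replicates by default); variant
scores use a hierarchical scheme that resamples (variant, depth, seed)
segments first, then frames within segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, balanced_accuracy_score,
                             matthews_corrcoef)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import DESCRIPTOR_COLUMNS, FeatureMatrix

__all__ = [
    "MODEL_NAMES",
    "CvFold",
    "CvResult",
    "VariantScore",
    "CalibrationReport",
    "lomo_split",
    "make_model",
    "fit_and_predict",
    "auroc",
    "bootstrap_ci",
    "aggregate_variant",
    "aggregate_all_variants",
    "calibration_report",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("lr", "svm", "rf", "mlp", "xgb")


@dataclass(frozen=True)
class CvFold:
    held_out_variant: str
    train_idx: np.ndarray
    test_idx: np.ndarray


def lomo_split(fm: FeatureMatrix) -> list[CvFold]:
    """One fold per distinct variant; test = that variant's frames."""
    variants = fm.variants
    uniq = sorted(pd.unique(variants))
    if len(uniq) < 2:
        raise ValueError("leave-one-mutation-out needs >= 2 distinct variants")
    if len(np.unique(fm.y)) < 2:
        raise ValueError("need both classes present overall")
    folds = []
    for v in uniq:
        test = np.flatnonzero(variants == v)
        train = np.flatnonzero(variants != v)
        folds.append(CvFold(held_out_variant=v, train_idx=train, test_idx=test))
    return folds


def make_model(name: str, rng_seed: int = 0, **overrides):
    """Classifier factory with the package's default hyperparameters, wrapped
    in a per-fold standardization pipeline."""
    if name == "lr":
        # default penalty is L2 with strength 1/C
        clf = LogisticRegression(C=1.0, max_iter=2000, random_state=rng_seed,
                                 **overrides)
    elif name == "svm":
        # Platt-scaled RBF SVM (sigmoid calibration on the decision values)
        clf = CalibratedClassifierCV(
            SVC(C=1.0, gamma="scale", kernel="rbf", random_state=rng_seed,
                **overrides),
            method="sigmoid", ensemble=False, cv=5)
    elif name == "rf":
        clf = RandomForestClassifier(n_estimators=500, random_state=rng_seed,
                                     n_jobs=1, **overrides)
    elif name == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(32, 16), activation="relu",
                            solver="adam", early_stopping=True, max_iter=500,
                            random_state=rng_seed, **overrides)
    elif name == "xgb":
        clf = XGBClassifier(n_estimators=300, max_depth=4, random_state=rng_seed,
                            eval_metric="logloss", n_jobs=1, verbosity=0,
                            **overrides)
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class CvResult:
    """Pooled out-of-fold predictions for one model."""

    model_name: str
    oof_probs: np.ndarray            # aligned with the feature-matrix rows
    auroc: float
    ci: tuple[float, float]
    n_bootstrap: int
    rng_seed: int
    fold_models: list = field(default_factory=list)


def fit_and_predict(folds: list[CvFold], fm: FeatureMatrix, model_name: str,
                    rng_seed: int = 0, n_bootstrap: int = 2000,
                    keep_models: bool = False) -> CvResult:
    """Train per fold on training rows only, record out-of-fold probabilities,
    and report pooled AUROC with a percentile bootstrap CI."""
    X, y = fm.X, fm.y
    oof = np.full(fm.n, np.nan)
    models = []
    for fold in folds:
        y_train = y[fold.train_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"training fold for held-out {fold.held_out_variant!r} is "
                "single-class; cannot fit a binary classifier")
        model = make_model(model_name, rng_seed=rng_seed)
        model.fit(X[fold.train_idx], y_train)
        oof[fold.test_idx] = model.predict_proba(X[fold.test_idx])[:, 1]
        if keep_models:
            models.append((fold.held_out_variant, model))
    assert not np.isnan(oof).any(), "some frames received no out-of-fold prediction"
    point = auroc(oof, y)
    df = pd.DataFrame({"prob": oof, "label": y})
    ci = bootstrap_ci(lambda d: auroc(d["prob"].to_numpy(), d["label"].to_numpy()),
                      df, n_replicates=n_bootstrap, rng_seed=rng_seed)
    return CvResult(model_name=model_name, oof_probs=oof, auroc=point, ci=ci,
                    n_bootstrap=n_bootstrap, rng_seed=rng_seed, fold_models=models)


def auroc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC: the Mann-Whitney statistic U / (n1 * n0), ties
    counted one half (midrank convention)."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(probabilities)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(statistic_fn: Callable[[pd.DataFrame], float],
                 data: pd.DataFrame, n_replicates: int = 2000,
                 rng_seed: int = 0, scheme: str = "frame",
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval of a statistic of a frame table.

    ``frame`` resamples rows i.i.d.; ``hierarchical`` resamples
    (variant, depth, seed) segments with replacement, then frames within
    each chosen segment. Replicates on which the statistic is undefined are
    redrawn (count logged).
    """
    if n_replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    if scheme not in ("frame", "hierarchical"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(rng_seed)
    n = len(data)
    stats = np.empty(n_replicates)
    segments = None
    if scheme == "hierarchical":
        cols = [c for c in ("variant", "depth", "seed") if c in data.columns]
        if not cols:
            raise ValueError("hierarchical scheme needs variant/depth/seed columns")
        seg_key = data[cols].astype(str).agg("|".join, axis=1).to_numpy()
        segments = [np.flatnonzero(seg_key == s) for s in pd.unique(seg_key)]
    redrawn = 0
    for b in range(n_replicates):
        while True:
            if scheme == "frame":
                idx = rng.integers(0, n, size=n)
            else:
                picked = rng.integers(0, len(segments), size=len(segments))
                idx = np.concatenate([
                    segments[s][rng.integers(0, len(segments[s]), size=len(segments[s]))]
                    for s in picked])
            try:
                stats[b] = statistic_fn(data.iloc[idx])
                break
            except ValueError:
                redrawn += 1
                if redrawn > 10 * n_replicates:
                    raise RuntimeError("statistic undefined on nearly all resamples")
    if redrawn:
        logger.info("bootstrap: %d resamples redrawn (statistic undefined)", redrawn)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class VariantScore:
    variant_id: str
    mean_prob: float
    ci: tuple[float, float]
    n_frames: int


def aggregate_variant(frame_table: pd.DataFrame, rng_seed: int = 0,
                      n_bootstrap: int = 2000) -> VariantScore:
    """Variant-level score: mean of the frame probabilities with a
    hierarchical bootstrap CI. ``frame_table`` holds one variant's frames
    with columns prob, variant, depth, seed."""
    if len(frame_table) == 0:
        raise ValueError("no frames for variant")
    variant = str(frame_table["variant"].iloc[0])
    mean = float(frame_table["prob"].mean())
    if frame_table["prob"].nunique() == 1:
        ci = (mean, mean)
    else:
        ci = bootstrap_ci(lambda d: float(d["prob"].mean()), frame_table,
                          n_replicates=n_bootstrap, rng_seed=rng_seed,
                          scheme="hierarchical")
    return VariantScore(variant_id=variant, mean_prob=mean, ci=ci,
                        n_frames=len(frame_table))


def aggregate_all_variants(fm: FeatureMatrix, probs: np.ndarray,
                           rng_seed: int = 0, n_bootstrap: int = 2000
                           ) -> pd.DataFrame:
    """Variant-score table for every variant in the feature matrix."""
    df = fm.data[["variant", "label", "depth", "seed"]].copy()
    df["prob"] = np.asarray(probs, dtype=float)
    rows = []
    for v, grp in df.groupby("variant", sort=True):
        score = aggregate_variant(grp, rng_seed=rng_seed, n_bootstrap=n_bootstrap)
        rows.append({"variant": v, "label": int(grp["label"].iloc[0]),
                     "mean_prob": score.mean_prob, "ci_lo": score.ci[0],
                     "ci_hi": score.ci[1], "n_frames": score.n_frames})
    return pd.DataFrame(rows)


@dataclass
class CalibrationReport:
    bin_edges: np.ndarray
    bin_mean_pred: np.ndarray     # NaN for empty bins
    bin_frac_pos: np.ndarray
    bin_counts: np.ndarray
    brier: float
    ece: float
    balanced_accuracy: float
    mcc: float
    auroc: float | None
    aupr: float | None
    threshold: float

    def reliability_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
            "mean_pred": self.bin_mean_pred, "frac_pos": self.bin_frac_pos,
            "count": self.bin_counts,
        })


def calibration_report(probs: np.ndarray, labels: np.ndarray,
                       n_bins: int = 10, threshold: float = 0.5
                       ) -> CalibrationReport:
    """Reliability analysis: equal-width bins, Brier, ECE, and thresholded
    balanced accuracy / MCC; AUROC and AUPR where both classes are present."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) == 0:
        raise ValueError("empty input")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    mean_pred = np.full(n_bins, np.nan)
    frac_pos = np.full(n_bins, np.nan)
    ece = 0.0
    n = len(probs)
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        sel = which == b
        mean_pred[b] = probs[sel].mean()
        frac_pos[b] = labels[sel].mean()
        ece += counts[b] / n * abs(mean_pred[b] - frac_pos[b])
    brier = float(np.mean((probs - labels) ** 2))
    pred = (probs >= threshold).astype(int)
    both = len(np.unique(labels)) == 2
    return CalibrationReport(
        bin_edges=edges, bin_mean_pred=mean_pred, bin_frac_pos=frac_pos,
        bin_counts=counts, brier=brier, ece=float(ece),
        balanced_accuracy=float(balanced_accuracy_score(labels, pred)) if both else float("nan"),
        mcc=float(matthews_corrcoef(labels, pred)),
        auroc=auroc(probs, labels) if both else None,
        aupr=float(average_precision_score(labels, probs)) if both else None,
        threshold=threshold,
    )
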
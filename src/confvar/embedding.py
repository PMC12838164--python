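"""Low-dimensional representations: PCA baseline and SPIB training helpers.

PCA on the standardized descriptors gives a deterministic, linearly
interpretable baseline. The SPIB route orders the ensemble as a
pseudo-trajectory (frames are exchangeable; ordering only defines lagged
prediction targets), seeds discrete states by k-means, and trains the
information-bottleneck model from :mod:`confvar.spib`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .features import FeatureMatrix
from .spib import LatentEmbedding, SpibConfig, encode, train_spib

__all__ = [
    "PcaResult",
    "pca_project",
    "make_pseudo_trajectory",
    "init_state_labels",
    "spib_embed",
    "SpibConfig",
    "LatentEmbedding",
    "train_spib",
    "encode",
]


@dataclass
class PcaResult:
    """Scores (N x k), orthonormal loadings (k x d) and variance ratios."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        r = self.explained_variance_ratio
        if np.any(np.diff(r) > 1e-10) or r.sum() > 1 + 1e-10:
            raise ValueError("variance ratios must be non-increasing and sum to <= 1")


def pca_project(X_std: np.ndarray, k: int = 2) -> PcaResult:
    """Project standardized features onto the first k principal components.

    Component signs are fixed so each loading's largest-magnitude entry is
    positive, making the decomposition fully deterministic.
    """
    X_std = np.asarray(X_std, dtype=float)
    if k > X_std.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X_std.shape[1]}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X_std)
    loadings = pca.components_
    signs = np.sign(loadings[np.arange(k), np.abs(loadings).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return PcaResult(
        scores=scores * signs,
        loadings=loadings * signs[:, None],
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def make_pseudo_trajectory(fm: FeatureMatrix, lag: int,
                           ordering: str = "provenance_sorted",
                           rng_seed: int = 0) -> np.ndarray:
    """Lagged (t, t+lag) frame-index pairs confined to contiguous segments.

    A segment is one (variant, depth, seed) block: frames from one
    generation run. Pairs never cross segment boundaries, so no spurious
    cross-variant "transitions" are created. ``shuffled_blocks`` permutes
    frame order within each segment before pairing.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if ordering not in ("provenance_sorted", "shuffled_blocks"):
        raise ValueError(f"unknown ordering {ordering!r}")
    seg = fm.segment_ids()
    rng = np.random.default_rng(rng_seed)
    pairs = []
    skipped = 0
    for s in pd.unique(seg):
        idx = np.flatnonzero(seg == s)
        if ordering == "shuffled_blocks":
            idx = rng.permutation(idx)
        if len(idx) < lag + 1:
            skipped += 1
            continue
        pairs.append(np.column_stack([idx[:-lag], idx[lag:]]))
    if skipped:
        warnings.warn(f"{skipped} segment(s) shorter than lag+1 were skipped")
    if not pairs:
        raise ValueError("every segment is shorter than lag+1; no pairs")
    return np.concatenate(pairs, axis=0)


def init_state_labels(X_std: np.ndarray, n_initial_states: int,
                      rng_seed: int = 0) -> np.ndarray:
    """Initial discrete states by seeded k-means; empty states are remapped
    away so labels are contiguous."""
    X_std = np.asarray(X_std, dtype=float)
    if n_initial_states < 2:
        raise ValueError("n_initial_states must be >= 2")
    if n_initial_states > len(X_std):
        raise ValueError("more initial states than frames")
    km = KMeans(n_clusters=n_initial_states, n_init=10, random_state=rng_seed)
    with warnings.catch_warnings():
        # duplicate rows can make k-means converge to fewer distinct centers
        warnings.simplefilter("ignore")
        labels = km.fit_predict(X_std)
    surviving = np.unique(labels)
    remap = {s: i for i, s in enumerate(surviving)}
    return np.array([remap[s] for s in labels])


def spib_embed(fm: FeatureMatrix, config: SpibConfig | None = None,
               ordering: str = "provenance_sorted") -> LatentEmbedding:
    """Full SPIB route on a standardized feature matrix: pseudo-trajectory,
    k-means state initialization, then information-bottleneck training."""
    config = config or SpibConfig()
    X = fm.X
    pairs = make_pseudo_trajectory(fm, config.lag, ordering=ordering,
                                   rng_seed=config.rng_seed)
    labels = init_state_labels(X, config.n_initial_states, rng_seed=config.rng_seed)
    return train_spib(pairs, X, labels, config)
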
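"""State Predictive Information Bottleneck (SPIB) on a pseudo-trajectory.

The model learns a stochastic 2-D encoder z ~ N(mu(x), sigma) and a softmax
decoder that predicts the discrete conformational state at a future lag tau.
The training objective is

    L = CE( decoder(z_t), state_{t+tau} ) + beta * KL( q(z|x) || N(0, I) )

with Gaussian input noise during training ("temporal noise regularization")
to prevent latent collapse. State labels start from k-means on the
standardized descriptors and are iteratively refined to the decoder's own
argmax prediction until fewer than a tolerance fraction of frames change.

Shallow ReLU feedforward networks, trained full-batch for up to 200 epochs
with a hand-rolled Adam optimizer (the nets are tiny: 5 -> 32 -> 2 and
2 -> 32 -> K). Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpibConfig", "LatentEmbedding", "train_spib", "encode"]


@dataclass
class SpibConfig:
    """Hyperparameters of the information-bottleneck embedding.

    lag is in frames of the pseudo-trajectory; beta weights the bottleneck
    divergence; noise_scale is in standardized feature units.
    """

    lag: int = 5
    latent_dim: int = 2
    n_initial_states: int = 6
    encoder_width: int = 32
    decoder_width: int = 32
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    beta: float = 1e-3
    noise_scale: float = 0.1
    refine_interval: int = 20
    refine_tol: float = 0.01      # fraction of frames allowed to change state
    patience: int = 20            # early stopping on the total objective
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.latent_dim < 1 or self.epochs < 1:
            raise ValueError("latent_dim and epochs must be >= 1")
        if self.beta < 0 or self.noise_scale < 0:
            raise ValueError("beta and noise_scale must be >= 0")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _init_params(d_in: int, cfg: SpibConfig, n_states: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    def glorot(shape):
        lim = np.sqrt(6.0 / sum(shape))
        return rng.uniform(-lim, lim, size=shape)

    h, g, k = cfg.encoder_width, cfg.decoder_width, cfg.latent_dim
    return {
        "W1": glorot((d_in, h)), "b1": np.zeros(h),
        "Wm": glorot((h, k)), "bm": np.zeros(k),
        "lv": np.full(k, -2.0),          # shared log-variance of the encoder
        "V1": glorot((k, g)), "c1": np.zeros(g),
        "V2": glorot((g, n_states)), "c2": np.zeros(n_states),
    }


def _encoder_mean(params: dict, X: np.ndarray) -> np.ndarray:
    h = _relu(X @ params["W1"] + params["b1"])
    return h @ params["Wm"] + params["bm"]


def _decode(params: dict, Z: np.ndarray) -> np.ndarray:
    d = _relu(Z @ params["V1"] + params["c1"])
    return _softmax(d @ params["V2"] + params["c2"])


@dataclass
class LatentEmbedding:
    """Trained SPIB state: deterministic coordinates, refined state labels,
    per-epoch loss log, and the frozen network parameters."""

    coords: np.ndarray               # (N, latent_dim) encoder means
    state_labels: np.ndarray         # (N,) ints in [0, n_states)
    n_states: int
    training_log: pd.DataFrame       # epoch, round, pred_loss, bottleneck, total
    params: dict[str, np.ndarray]
    config: SpibConfig
    d_in: int

    def predict_state(self, X_std: np.ndarray) -> np.ndarray:
        probs = _decode(self.params, _encoder_mean(self.params, np.asarray(X_std, float)))
        return np.argmax(probs, axis=1)


def _epoch_step(params, opt, X_in, y, cfg, rng, n_states):
    """One epoch of shuffled minibatch updates; returns mean (pred_loss, bottleneck)."""
    order = rng.permutation(len(X_in))
    ces, kls, sizes = [], [], []
    for start in range(0, len(order), cfg.batch_size):
        sel = order[start:start + cfg.batch_size]
        ce, kl = _batch_step(params, opt, X_in[sel], y[sel], cfg, rng, n_states)
        ces.append(ce)
        kls.append(kl)
        sizes.append(len(sel))
    w = np.asarray(sizes, float) / sum(sizes)
    return float(np.dot(ces, w)), float(np.dot(kls, w))


def _batch_step(params, opt, X_in, y, cfg, rng, n_states):
    B = len(X_in)
    Xn = X_in + cfg.noise_scale * rng.standard_normal(X_in.shape)
    pre1 = Xn @ params["W1"] + params["b1"]
    h1 = _relu(pre1)
    mu = h1 @ params["Wm"] + params["bm"]
    sig = np.exp(0.5 * params["lv"])
    eps = rng.standard_normal(mu.shape)
    z = mu + sig * eps
    pre2 = z @ params["V1"] + params["c1"]
    d1 = _relu(pre2)
    logits = d1 @ params["V2"] + params["c2"]
    probs = _softmax(logits)
    onehot = np.zeros((B, n_states))
    onehot[np.arange(B), y] = 1.0
    ce = -np.mean(np.log(probs[np.arange(B), y] + 1e-300))
    kl = 0.5 * (np.mean(np.sum(mu ** 2, axis=1))
                + np.sum(np.exp(params["lv"]) - params["lv"] - 1.0))

    dlogits = (probs - onehot) / B
    g = {}
    g["V2"] = d1.T @ dlogits
    g["c2"] = dlogits.sum(axis=0)
    dd1 = dlogits @ params["V2"].T
    dpre2 = dd1 * (pre2 > 0)
    g["V1"] = z.T @ dpre2
    g["c1"] = dpre2.sum(axis=0)
    dz = dpre2 @ params["V1"].T
    dmu = dz + cfg.beta * mu / B
    g["lv"] = (0.5 * np.sum(dz * eps, axis=0) * sig
               + cfg.beta * 0.5 * (np.exp(params["lv"]) - 1.0))
    g["Wm"] = h1.T @ dmu
    g["bm"] = dmu.sum(axis=0)
    dh1 = dmu @ params["Wm"].T
    dpre1 = dh1 * (pre1 > 0)
    g["W1"] = Xn.T @ dpre1
    g["b1"] = dpre1.sum(axis=0)
    opt.step(params, g)
    if not (np.isfinite(ce) and np.isfinite(kl)):
        raise FloatingPointError(f"non-finite SPIB loss (ce={ce}, kl={kl})")
    return ce, kl


def train_spib(pairs: np.ndarray, X_std: np.ndarray, labels: np.ndarray,
               config: SpibConfig) -> LatentEmbedding:
    """Train SPIB from lagged (t, t+tau) index pairs.

    ``pairs`` is an (M, 2) array of frame indices into ``X_std``;
    ``labels`` the initial per-frame discrete states. Collapse to a single
    surviving state is legal and reported via ``n_states``.
    """
    X_std = np.asarray(X_std, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    if len(pairs) == 0:
        raise ValueError("no lag pairs to train on")
    labels = np.asarray(labels, dtype=int).copy()
    rng = np.random.default_rng(config.rng_seed)
    n_states = int(labels.max()) + 1
    params = _init_params(X_std.shape[1], config, n_states, rng)
    opt = _Adam(params, config.learning_rate)

    X_in = X_std[pairs[:, 0]]
    log_rows = []
    best, since_best = np.inf, 0
    round_id = 0
    for epoch in range(config.epochs):
        y = labels[pairs[:, 1]]
        ce, kl = _epoch_step(params, opt, X_in, y, config, rng, n_states)
        total = ce + config.beta * kl
        log_rows.append({"epoch": epoch, "round": round_id,
                         "pred_loss": ce, "bottleneck": kl, "total": total})
        if total < best - 1e-9:
            best, since_best = total, 0
        else:
            since_best += 1
        end_of_round = (epoch + 1) % config.refine_interval == 0
        if end_of_round:
            new = _decode(params, _encoder_mean(params, X_std)).argmax(axis=1)
            changed = np.mean(new != labels)
            labels = new
            round_id += 1
            if changed < config.refine_tol:
                break
        if since_best >= config.patience:
            break

    # drop empty states and remap contiguously
    surviving = np.unique(labels)
    remap = {s: i for i, s in enumerate(surviving)}
    labels = np.array([remap[s] for s in labels])
    return LatentEmbedding(
        coords=_encoder_mean(params, X_std),
        state_labels=labels,
        n_states=len(surviving),
        training_log=pd.DataFrame(log_rows),
        params=params,
        config=config,
        d_in=X_std.shape[1],
    )


def encode(X_new: np.ndarray, embedding: LatentEmbedding) -> np.ndarray:
    """Deterministic encoder means for new standardized data (frozen model)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != embedding.d_in:
        raise ValueError(f"expected (n, {embedding.d_in}) input, got {X_new.shape}")
    return _encoder_mean(embedding.params, X_new)
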
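"""Att-RethinkNet: recurrent multi-label "rethinking" with feature attention.

The model treats multi-label prediction as a short sequence task: the same
input vector is fed to a recurrent cell for T steps, each step's hidden
state is decoded by a shared dense sigmoid head into a tentative label
score vector, and the recurrent memory carries the previous step's
tentative prediction into the next — iteratively polishing the label set.
The final step's scores are the prediction. Because all weights are shared
across steps, the trainable parameter count does not depend on T.

An attention block sits between the input and the recurrent layer: a dense
map over the feature axis followed by softmax yields per-sample,
per-gene probabilities that rescale the input elementwise, letting the
network emphasise informative genes. (A step-axis variant, softmax over
the T replicated steps, is provided for comparison; its dense map is T x T
so its parameter count does depend on T.)

Training minimises a cost-sensitive re-weighted binary cross-entropy:
each label l carries a weight w_l (by default inverse prevalence,
normalised to mean 1), averaged over samples, rethinking steps and labels.
Everything is plain numpy with hand-derived gradients (validated in the
test suite against numerical differentiation); optimisation is Adam on
shuffled minibatches with a seeded generator, so a fixed seed reproduces
runs exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MultiLabelDataset, ValidationError

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class RethinkConfig:
    T: int = 5
    cell: str = "lstm"                      # or "srn"
    hidden_units: int = 32
    attention: str = "feature_axis"         # "step_axis" or "off"
    label_weights: str | np.ndarray = "inverse_frequency"  # or "uniform" / explicit
    weight_cap: float = 50.0
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 0.005
    lr_decay_milestones: tuple[float, float] = (0.6, 0.85)  # fractions of epochs
    lr_decay_factor: float = 0.1
    weight_decay: float = 0.05
    attention_l2: float = 1.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ConfigurationError("T must be >= 1")
        if self.cell not in ("lstm", "srn"):
            raise ConfigurationError(f"cell must be lstm or srn, got {self.cell!r}")
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if self.attention not in ("feature_axis", "step_axis", "off"):
            raise ConfigurationError(f"unknown attention mode {self.attention!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must be in (0, 1)")
        if isinstance(self.label_weights, str):
            if self.label_weights not in ("inverse_frequency", "uniform"):
                raise ConfigurationError(f"unknown label_weights {self.label_weights!r}")
        else:
            w = np.asarray(self.label_weights, dtype=float)
            if w.ndim != 1 or (w <= 0).any():
                raise ConfigurationError("explicit label_weights must be a positive vector")


@dataclass
class RethinkTrace:
    """Per-iteration score sequence and the thresholded final labels."""

    scores: np.ndarray        # (n, T, L), entries in (0, 1)
    final_labels: np.ndarray  # (n, L) binary, 1[scores[:, -1] >= threshold]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class AttRethinkNet:
    """Model handle holding parameters, built for a fixed (dim, L)."""

    def __init__(self, cfg: RethinkConfig, dim: int, L: int):
        if dim < 1:
            raise ConfigurationError("dim must be >= 1")
        if L < 1:
            raise ConfigurationError("L must be >= 1")
        self.cfg = cfg
        self.dim = dim
        self.L = L
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden_units
        self.params: dict[str, np.ndarray] = {}
        p = self.params
        if cfg.attention == "feature_axis":
            p["W_a"] = rng.normal(0, 1.0 / np.sqrt(dim), (dim, dim))
            p["b_a"] = np.zeros(dim)
        elif cfg.attention == "step_axis":
            p["W_s"] = rng.normal(0, 1.0 / np.sqrt(cfg.T), (cfg.T, cfg.T))
            p["b_s"] = np.zeros(cfg.T)
        if cfg.cell == "lstm":
            p["W_x"] = rng.normal(0, 1.0 / np.sqrt(dim), (dim, 4 * H))
            p["W_h"] = rng.normal(0, 1.0 / np.sqrt(H), (H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            p["b"] = b
        else:
            p["W_x"] = rng.normal(0, 1.0 / np.sqrt(dim), (dim, H))
            p["W_h"] = rng.normal(0, 1.0 / np.sqrt(H), (H, H))
            p["b"] = np.zeros(H)
        p["W_y"] = rng.normal(0, 1.0 / np.sqrt(H), (H, L))
        p["b_y"] = np.zeros(L)
        self.label_weight_vector: np.ndarray | None = None
        self.loss_history: list[float] = []
        self._rng = rng

    # ---------------------------------------------------------------- forward

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _attention_forward(self, X):
        """Returns (x_steps, cache). x_steps is (B, T, D) after weighting."""
        cfg, p = self.cfg, self.params
        B = X.shape[0]
        if cfg.attention == "off":
            x_steps = np.broadcast_to(X[:, None, :], (B, cfg.T, self.dim))
            return x_steps, {"mode": "off"}
        if cfg.attention == "feature_axis":
            z = X @ p["W_a"] + p["b_a"]
            a = _softmax(z, axis=1)                       # (B, D), sums to 1
            # multiply by mean-1 weights (D * a) so the block preserves the
            # input scale; uniform attention is then the identity
            xw = X * (self.dim * a)
            x_steps = np.broadcast_to(xw[:, None, :], (B, cfg.T, self.dim))
            return x_steps, {"mode": "feature_axis", "a": a, "X": X}
        # step_axis: permute (B,T,D)->(B,D,T), dense T->T, softmax over T,
        # permute back, multiply
        v = np.broadcast_to(X[:, :, None], (B, self.dim, cfg.T))
        z = v @ p["W_s"] + p["b_s"]                       # (B, D, T)
        a = _softmax(z, axis=2)
        x_steps = (v * a).transpose(0, 2, 1)              # (B, T, D)
        return x_steps, {"mode": "step_axis", "a": a, "v": v, "X": X}

    def _recurrent_forward(self, x_steps):
        cfg, p = self.cfg, self.params
        B = x_steps.shape[0]
        H = cfg.hidden_units
        cache = {"x": x_steps, "h": [], "c": [], "gates": []}
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = []
        for t in range(cfg.T):
            xt = x_steps[:, t, :]
            if cfg.cell == "lstm":
                zs = xt @ p["W_x"] + h @ p["W_h"] + p["b"]
                i = _sigmoid(zs[:, :H])
                f = _sigmoid(zs[:, H:2 * H])
                g = np.tanh(zs[:, 2 * H:3 * H])
                o = _sigmoid(zs[:, 3 * H:])
                c_new = f * c + i * g
                h_new = o * np.tanh(c_new)
                cache["gates"].append((i, f, g, o))
                cache["c"].append((c, c_new))
                cache["h"].append(h)
                h, c = h_new, c_new
            else:
                zs = xt @ p["W_x"] + h @ p["W_h"] + p["b"]
                h_new = np.tanh(zs)
                cache["h"].append(h)
                cache["gates"].append(h_new)
                h = h_new
            hs.append(h)
        cache["hs"] = hs
        return np.stack(hs, axis=1), cache    # (B, T, H)

    def forward(self, X, with_cache: bool = False):
        """Scores shaped (B, T, L) in (0, 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.dim:
            raise ValidationError(f"expected features of dim {self.dim}, got {X.shape}")
        x_steps, att_cache = self._attention_forward(X)
        hs, rec_cache = self._recurrent_forward(x_steps)
        logits = hs @ self.params["W_y"] + self.params["b_y"]  # (B, T, L)
        scores = _sigmoid(logits)
        if with_cache:
            return scores, {"att": att_cache, "rec": rec_cache, "hs": hs}
        return scores

    def attention_probabilities(self, X) -> np.ndarray:
        """Softmax attention weights per sample ((B, D) in feature mode)."""
        if self.cfg.attention == "off":
            raise ConfigurationError("attention is off; no attention block to query")
        X = np.asarray(X, dtype=float)
        _, cache = self._attention_forward(X)
        return cache["a"]

    # --------------------------------------------------------------- backward

    def _backward(self, X, Y, scores, cache, w):
        """Gradients of the weighted mean BCE w.r.t. every parameter."""
        cfg, p = self.cfg, self.params
        B, T, L = scores.shape
        H = cfg.hidden_units
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # dL/dlogit for sigmoid + BCE, averaged over B*T*L with label weights
        dlogits = w[None, None, :] * (scores - Y[:, None, :]) / (B * T * L)
        hs = cache["hs"]
        grads["W_y"] = np.einsum("bth,btl->hl", hs, dlogits)
        grads["b_y"] = dlogits.sum(axis=(0, 1))
        dhs = dlogits @ p["W_y"].T                          # (B, T, H)

        rec = cache["rec"]
        x_steps = rec["x"]
        dx_steps = np.zeros((B, T, self.dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dhs[:, t, :] + dh_next
            xt = x_steps[:, t, :]
            h_prev = rec["h"][t]
            if cfg.cell == "lstm":
                i, f, g, o = rec["gates"][t]
                c_prev, c_new = rec["c"][t]
                tanh_c = np.tanh(c_new)
                do = dh * tanh_c
                dc = dh * o * (1 - tanh_c**2) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dzi = di * i * (1 - i)
                dzf = df * f * (1 - f)
                dzg = dg * (1 - g**2)
                dzo = do * o * (1 - o)
                dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
                dc_next = dc * f
            else:
                h_new = rec["gates"][t]
                dz = dh * (1 - h_new**2)
                dc_next = np.zeros((B, H))
            grads["W_x"] += xt.T @ dz
            grads["W_h"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dx_steps[:, t, :] = dz @ p["W_x"].T
            dh_next = dz @ p["W_h"].T

        att = cache["att"]
        if att["mode"] == "off":
            pass
        elif att["mode"] == "feature_axis":
            a = att["a"]
            gsum = dx_steps.sum(axis=1)                     # x' shared across steps
            da = gsum * X * self.dim
            dz = a * (da - (da * a).sum(axis=1, keepdims=True))
            grads["W_a"] = X.T @ dz
            grads["b_a"] = dz.sum(axis=0)
            # dX = multiply path + attention-input path (unused upstream)
        else:
            a = att["a"]                                    # (B, D, T)
            v = att["v"]
            dxp = dx_steps.transpose(0, 2, 1)               # (B, D, T)
            da = dxp * v
            dz = a * (da - (da * a).sum(axis=2, keepdims=True))
            grads["W_s"] = np.einsum("bdt,bdu->tu", v, dz)
            grads["b_s"] = dz.sum(axis=(0, 1))
        return grads

    # --------------------------------------------------------------- training

    def loss(self, X, Y, w=None):
        scores = self.forward(X)
        return self._loss_from_scores(scores, Y, w)

    def _loss_from_scores(self, scores, Y, w=None):
        if w is None:
            w = np.ones(self.L)
        eps = 1e-12
        s = np.clip(scores, eps, 1 - eps)
        Yb = np.asarray(Y, dtype=float)[:, None, :]
        bce = -(Yb * np.log(s) + (1 - Yb) * np.log(1 - s))
        return float((w[None, None, :] * bce).mean())


def label_weight_vector(cfg: RethinkConfig, labels: np.ndarray) -> np.ndarray:
    """Cost weights w_l: inverse prevalence normalised to mean 1 by default."""
    labels = np.asarray(labels)
    L = labels.shape[1]
    if isinstance(cfg.label_weights, str):
        if cfg.label_weights == "uniform":
            return np.ones(L)
        counts = labels.sum(axis=0).astype(float)
        n = labels.shape[0]
        zero = counts == 0
        if zero.any():
            log.warning("%d label(s) with zero positives; weight clamped at cap", int(zero.sum()))
        raw = n / np.where(zero, 1.0, counts)
        raw = np.minimum(raw, cfg.weight_cap)
        return raw / raw.mean()
    w = np.asarray(cfg.label_weights, dtype=float)
    if w.shape != (L,):
        raise ConfigurationError(f"explicit label_weights length {w.shape} != L={L}")
    return w


def build_model(cfg: RethinkConfig, dim: int, L: int) -> AttRethinkNet:
    """Construct an untrained model handle for the given input/label sizes."""
    return AttRethinkNet(cfg, dim, L)


def train(
    model: AttRethinkNet,
    dataset: MultiLabelDataset,
    cfg: RethinkConfig | None = None,
) -> tuple[AttRethinkNet, list[float]]:
    """Adam training on shuffled minibatches; returns (model, loss history).

    The history holds one weighted mean-BCE value per epoch (computed over
    the minibatch losses of that epoch). Same seed, single-threaded ->
    identical history.
    """
    cfg = cfg or model.cfg
    X = dataset.features
    Y = dataset.labels.astype(float)
    if X.shape[1] != model.dim or Y.shape[1] != model.L:
        raise ValidationError(
            f"dataset (dim={X.shape[1]}, L={Y.shape[1]}) does not match "
            f"model (dim={model.dim}, L={model.L})"
        )
    w = label_weight_vector(cfg, dataset.labels)
    model.label_weight_vector = w

    rng = np.random.default_rng(cfg.seed + 1)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = X.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * (
            cfg.lr_decay_factor ** sum(epoch >= d * cfg.epochs for d in cfg.lr_decay_milestones)
        )
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            scores, cache = model.forward(xb, with_cache=True)
            epoch_losses.append(model._loss_from_scores(scores, yb, w))
            grads = model._backward(xb, yb, scores, cache, w)
            # L2 on the attention map keeps the learned weighting close to
            # uniform unless the data support genuine feature importance
            if cfg.attention_l2 > 0:
                for k in ("W_a", "b_a", "W_s", "b_s"):
                    if k in grads:
                        grads[k] = grads[k] + cfg.attention_l2 * model.params[k]
            step += 1
            for k in model.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v_adam[k] / (1 - beta2**step)
                update = mhat / (np.sqrt(vhat) + eps)
                if not k.startswith("b"):  # decoupled decay on weights, not biases
                    update = update + cfg.weight_decay * model.params[k]
                model.params[k] -= lr * update
        history.append(float(np.mean(epoch_losses)))
    model.loss_history = history
    return model, history


def predict(model: AttRethinkNet, features: np.ndarray) -> RethinkTrace:
    """Run the T rethinking iterations and threshold the final scores."""
    scores = model.forward(features)
    final = (scores[:, -1, :] >= model.cfg.threshold).astype(np.int64)
    return RethinkTrace(scores=scores, final_labels=final)
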
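"""Regression ANNs over N=56 diameter profiles for the three vascular
components.

One model per component kind:

* bifurcation: inputs u_m, H_m and the area ratios (d1/dm)^2, (d2/dm)^2;
  outputs u and H in both daughters (apex-first orientation).
* vessel: inputs u, H at the vessel entrance plus diameter d and length l;
  outputs u, H at the vessel end.
* merger: inputs u, H in both parent vessels plus area ratios; outputs u, H
  in the merged vessel.

Scalar inputs are broadcast to length-N vectors and concatenated with the
velocity profile before the first hidden layer; the hematocrit profile is
concatenated with the first hidden layer's output. All hidden layers are
ReLU with dropout; the output layer is linear. Training uses per-sample
(batch size 1) Adam updates in a seed-determined random order per epoch,
with the loss

    MSE_u = sum_i (u_i - u_i^pred)^2 / N
    MSE_H = sum_i (H_i - H_i^pred)^2 / (N * max_i H_i^2)

summed over all output profiles of the component.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import Adam, dropout_mask, he_init, relu, relu_grad
from .errors import ModelStateError
from .prep import (ComponentSample, KIND_HEMATOCRIT, KIND_VELOCITY,
                   ORIENT_APEX, ORIENT_GLOBAL, Profile1D)

__all__ = ["Ann2DConfig", "Ann2D", "build_ann", "train_2d",
           "predict_component_2d", "loss_mse_velocity",
           "loss_mse_hematocrit"]

_DEFAULT_HIDDEN = {"bifurcation": 7, "vessel": 7, "merger": 10}

# profile keys feeding the velocity block / hematocrit block, and outputs
_LAYOUT = {
    "bifurcation": (("u_m",), ("a1", "a2"), ("H_m",),
                    ("u_1", "H_1", "u_2", "H_2")),
    "vessel": (("u_in",), ("d", "l"), ("H_in",), ("u_out", "H_out")),
    "merger": (("u_1", "u_2"), ("a1", "a2"), ("H_1", "H_2"),
               ("u_out", "H_out")),
}


def loss_mse_velocity(u_true, u_pred) -> float:
    """Mean squared error over the N collocation points."""
    u_true = np.asarray(u_true, dtype=float)
    u_pred = np.asarray(u_pred, dtype=float)
    if u_true.shape != u_pred.shape:
        raise ValueError("profile length mismatch")
    return float(np.mean((u_true - u_pred) ** 2))


def loss_mse_hematocrit(h_true, h_pred) -> float:
    """Squared error normalized by N times the maximum squared true
    hematocrit."""
    h_true = np.asarray(h_true, dtype=float)
    h_pred = np.asarray(h_pred, dtype=float)
    if h_true.shape != h_pred.shape:
        raise ValueError("profile length mismatch")
    norm = float(np.max(h_true ** 2))
    if norm == 0.0:
        raise ValueError("degenerate normalization: all-zero true hematocrit")
    return float(np.sum((h_true - h_pred) ** 2) / (h_true.size * norm))


@dataclass
class Ann2DConfig:
    component_kind: str
    n: int = 56
    hidden_layers: int | None = None     # default 7 (10 for mergers)
    width: int = 80
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.component_kind not in _LAYOUT:
            raise ValueError(f"unknown component kind {self.component_kind!r}")
        if self.hidden_layers is None:
            self.hidden_layers = _DEFAULT_HIDDEN[self.component_kind]
        if self.hidden_layers < 1 or self.width < 1:
            raise ValueError("hidden_layers and width must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


class Ann2D:
    """A (possibly trained) 2D component model: weights, config, input
    normalization constants and loss history."""

    def __init__(self, config: Ann2DConfig):
        self.config = config
        u_keys, s_keys, h_keys, out_keys = _LAYOUT[config.component_kind]
        self.u_keys, self.s_keys, self.h_keys = u_keys, s_keys, h_keys
        self.out_keys = out_keys
        n, w = config.n, config.width
        self.in0 = n * (len(u_keys) + len(s_keys))
        self.inh = n * len(h_keys)
        self.out_dim = n * len(out_keys)
        rng = np.random.default_rng(config.seed)
        dims = [(w, self.in0), (w, w + self.inh)]
        dims += [(w, w)] * (config.hidden_layers - 2)
        dims += [(self.out_dim, w)]
        shapes: list[tuple[int, ...]] = []
        for dout, din in dims:
            shapes += [(dout, din), (dout,)]
        # all parameters live in one flat vector so the optimizer update is
        # a single set of vectorized operations
        total = sum(int(np.prod(s)) for s in shapes)
        self.theta = np.zeros(total, dtype=np.float32)
        self._grad = np.zeros(total, dtype=np.float32)
        self.params: list[np.ndarray] = []
        self._gviews: list[np.ndarray] = []
        off = 0
        for s in shapes:
            size = int(np.prod(s))
            self.params.append(self.theta[off:off + size].reshape(s))
            self._gviews.append(self._grad[off:off + size].reshape(s))
            off += size
        for i, (dout, din) in enumerate(dims):
            self.params[2 * i][...] = he_init(rng, (dout, din), din)
        self.norm: dict[str, np.ndarray] = {}
        self.loss_history: list[float] = []
        self.trained = False

    # ------------------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def _vectors(self, sample_inputs: dict, scalars: dict):
        """Raw (un-normalized) velocity-block and hematocrit-block vectors."""
        n = self.config.n
        parts0 = [np.asarray(sample_inputs[k].values, dtype=float)
                  for k in self.u_keys]
        parts0 += [np.full(n, float(scalars[k])) for k in self.s_keys]
        partsh = [np.asarray(sample_inputs[k].values, dtype=float)
                  for k in self.h_keys]
        return np.concatenate(parts0), np.concatenate(partsh)

    def _fit_norm(self, x0s: np.ndarray, xhs: np.ndarray) -> None:
        """Per-feature standardization with a relative floor on the scale.

        The floor (1% of the pooled std of the feature's profile block)
        matters: wall collocation points of every training velocity profile
        are exactly zero, and an absolute epsilon floor there would amplify
        harmless near-wall deviations of *predicted* profiles by orders of
        magnitude when predictions are chained during network traversal."""
        n = self.config.n

        def stats(x):
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            for j in range(x.shape[1] // n):
                seg = slice(j * n, (j + 1) * n)
                floor = max(0.01 * x[:, seg].std(), 1e-8)
                sd[seg] = np.maximum(sd[seg], floor)
            return mu, sd

        mu0, sd0 = stats(x0s)
        muh, sdh = stats(xhs)
        self.norm = {"mu0": mu0, "sd0": sd0, "muh": muh, "sdh": sdh}

    def _normalize(self, x0, xh):
        if not self.norm:
            raise ModelStateError("normalization constants not fitted")
        return ((x0 - self.norm["mu0"]) / self.norm["sd0"],
                (xh - self.norm["muh"]) / self.norm["sdh"])

    # ------------------------------------------------------------------
    def _forward(self, x0, xh, rng=None):
        """Forward pass; dropout is active iff ``rng`` is given."""
        cfg = self.config
        p = self.params
        acts, masks, pre = [], [], []
        h = None
        x_in = x0
        n_hidden = cfg.hidden_layers
        for layer in range(n_hidden):
            wt, b = p[2 * layer], p[2 * layer + 1]
            if layer == 1:
                x_in = np.concatenate([h, xh])
            elif layer > 1:
                x_in = h
            z = wt @ x_in + b
            h = relu(z)
            m = dropout_mask(rng, h.shape, cfg.dropout_rate, dtype=h.dtype) \
                if rng is not None else None
            if m is not None:
                h = h * m
            acts.append(x_in)
            pre.append(z)
            masks.append(m)
        wt, b = p[-2], p[-1]
        y = wt @ h + b
        return y, (acts, pre, masks, h)

    def _backward(self, dy, cache):
        """Accumulate gradients into the flat gradient buffer (returned)."""
        acts, pre, masks, h_last = cache
        p = self.params
        grads = self._gviews
        np.outer(dy, h_last, out=grads[-2])
        grads[-1][...] = dy
        dh = p[-2].T @ dy
        n_hidden = self.config.hidden_layers
        for layer in range(n_hidden - 1, -1, -1):
            if masks[layer] is not None:
                dh = dh * masks[layer]
            dz = dh * relu_grad(pre[layer])
            np.outer(dz, acts[layer], out=grads[2 * layer])
            grads[2 * layer + 1][...] = dz
            dx = p[2 * layer].T @ dz
            if layer >= 2:
                dh = dx
            elif layer == 1:
                dh = dx[:self.config.width]
            # layer 0: gradient w.r.t. raw inputs not needed
        return self._grad

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "trained": self.trained,
                "loss_history": self.loss_history}
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        arrays.update({f"norm_{k}": v for k, v in self.norm.items()})
        np.savez_compressed(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Ann2D":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(Ann2DConfig(**meta["config"]))
            for i in range(len(model.params)):
                model.params[i][...] = data[f"p{i}"]
            model.norm = {k[len("norm_"):]: data[k].copy() for k in data.files
                          if k.startswith("norm_")}
            model.loss_history = list(meta["loss_history"])
            model.trained = meta["trained"]
        return model


def build_ann(config: Ann2DConfig) -> Ann2D:
    """Build an untrained component ANN from its configuration."""
    return Ann2D(config)


def _sample_loss_and_grad(model: Ann2D, y_pred, target):
    """Combined loss and its gradient w.r.t. the prediction vector."""
    n = model.config.n
    loss = 0.0
    dy = np.zeros_like(y_pred)
    for j, key in enumerate(model.out_keys):
        sl = slice(j * n, (j + 1) * n)
        t, pr = target[sl], y_pred[sl]
        if key.startswith("u"):
            loss += np.mean((t - pr) ** 2)
            dy[sl] = 2.0 * (pr - t) / n
        else:
            norm = max(float(np.max(t ** 2)), 1e-12)
            loss += np.sum((t - pr) ** 2) / (n * norm)
            dy[sl] = 2.0 * (pr - t) / (n * norm)
    return float(loss), dy


def train_2d(model: Ann2D, samples: list[ComponentSample],
             epochs: int | None = None) -> Ann2D:
    """Train with per-sample Adam updates in a seed-determined random order
    per epoch. Returns the same model, trained in place."""
    if not samples:
        raise ValueError("empty sample list")
    kind = model.config.component_kind
    if any(s.component_kind != kind for s in samples):
        raise ValueError("mixed component kinds in training samples")
    epochs = model.config.epochs if epochs is None else epochs

    x0s = []
    xhs = []
    targets = []
    n = model.config.n
    for s in samples:
        x0, xh = model._vectors(s.inputs, s.scalars)
        x0s.append(x0)
        xhs.append(xh)
        targets.append(np.concatenate(
            [np.asarray(s.outputs[k].values, dtype=float)
             for k in model.out_keys]))
        if x0.size != model.in0 or targets[-1].size != model.out_dim:
            raise ValueError("sample does not match the model contract")
    x0s, xhs = np.asarray(x0s), np.asarray(xhs)
    if not model.norm:
        model._fit_norm(x0s, xhs)
    x0n = ((x0s - model.norm["mu0"]) / model.norm["sd0"]).astype(np.float32)
    xhn = ((xhs - model.norm["muh"]) / model.norm["sdh"]).astype(np.float32)
    targets = [t.astype(np.float32) for t in targets]

    rng = np.random.default_rng(model.config.seed + 1)
    opt = Adam([model.theta], lr=model.config.learning_rate)
    for _ in range(epochs):
        order = rng.permutation(len(samples))
        epoch_loss = 0.0
        for i in order:
            y, cache = model._forward(x0n[i], xhn[i], rng=rng)
            loss, dy = _sample_loss_and_grad(model, y, targets[i])
            gflat = model._backward(dy, cache)
            opt.step([gflat])
            epoch_loss += loss
        model.loss_history.append(epoch_loss / len(samples))
    model.trained = True
    return model


def predict_component_2d(model: Ann2D,
                         sample: ComponentSample | None = None,
                         inputs: dict | None = None,
                         scalars: dict | None = None
                         ) -> dict[str, Profile1D]:
    """Deterministic inference (dropout disabled). Returns one Profile1D per
    output key; daughter outputs of a bifurcation are apex-first."""
    if not model.trained:
        raise ModelStateError("model has not been trained")
    if sample is not None:
        inputs, scalars = sample.inputs, sample.scalars
    if inputs is None or scalars is None:
        raise ValueError("either a sample or inputs+scalars must be given")
    x0, xh = model._vectors(inputs, scalars)
    x0n, xhn = model._normalize(x0, xh)
    y, _ = model._forward(x0n, xhn, rng=None)
    n = model.config.n
    xi = next(iter(inputs.values())).xi
    orient = ORIENT_APEX if model.config.component_kind == "bifurcation" \
        else ORIENT_GLOBAL
    out = {}
    for j, key in enumerate(model.out_keys):
        vals = y[j * n:(j + 1) * n]
        if key.startswith("H"):
            out[key] = Profile1D(xi.copy(), np.clip(vals, 0.0, 1.0),
                                 KIND_HEMATOCRIT, orient)
        else:
            out[key] = Profile1D(xi.copy(), np.clip(vals, 0.0, None),
                                 KIND_VELOCITY, orient)
    return out
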
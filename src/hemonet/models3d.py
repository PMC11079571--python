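"""Convolutional U-net component models over 32 x 32 cross-sectional fields.

Each model maps upstream (u, H) field pairs to downstream field pairs.
The encoder applies, per level, two 3x3 convolutions (ReLU) followed by 2x2
max-pooling, halving the grid until it is flattened; the flattened bottleneck
is concatenated with the geometric conditioning scalars (d1/dm, d2/dm and
the augmentation angle delta_beta for junctions; d, l, delta_beta for
vessels) and mixed by a dense ReLU layer. The decoder applies, per level, a
2x2 transposed convolution (stride 2, ReLU), concatenation with the matching
encoder feature map, and a 3x3 convolution (ReLU). A linear 3x3 convolution
produces the output channels (u, H — four channels for the two bifurcation
daughters), which are masked to the lumen disc.

Training minimizes the masked per-sample loss

    MSE_u = sum_cells (u - u_pred)^2 / M
    MSE_H = sum_cells (H - H_pred)^2 / (M * max H^2)

summed over output channels (M = number of in-mask cells), with Adam under a
piecewise-constant learning-rate schedule.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import (Adam, conv3x3_backward, conv3x3_forward, convT2x2_backward,
                  convT2x2_forward, he_init, maxpool2_backward,
                  maxpool2_forward, relu, relu_grad)
from .errors import ModelStateError
from .prep import ComponentSample, Field2D, KIND_HEMATOCRIT, KIND_VELOCITY

__all__ = ["UnetConfig", "Unet3D", "build_unet", "train_3d",
           "predict_component_3d", "mae", "MERGER_LR_SCHEDULE"]

#: the merger learning-rate schedule at full scale: (epochs, learning rate)
MERGER_LR_SCHEDULE: tuple[tuple[int, float], ...] = (
    (50_000, 5e-4), (30_000, 1e-4), (30_000, 5e-5))

_CHANNELS = {
    "bifurcation": (("u_m", "H_m"), ("u_1", "H_1", "u_2", "H_2"),
                    ("r1", "r2", "delta_beta")),
    "vessel": (("u_in", "H_in"), ("u_out", "H_out"), ("d", "l", "delta_beta")),
    "merger": (("u_1", "H_1", "u_2", "H_2"), ("u_out", "H_out"),
               ("r1", "r2", "delta_beta")),
}


@dataclass
class UnetConfig:
    component_kind: str
    ng: int = 32
    levels: int = 5
    base_filters: int = 16
    lr_schedule: tuple[tuple[int, float], ...] = ((60_000, 5e-4),)
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.component_kind not in _CHANNELS:
            raise ValueError(f"unknown component kind {self.component_kind!r}")
        if self.ng % (2 ** self.levels) != 0:
            raise ValueError(
                f"grid size {self.ng} is not divisible by 2^{self.levels}")
        self.lr_schedule = tuple((int(n), float(lr))
                                 for n, lr in self.lr_schedule)
        if any(n <= 0 for n, _ in self.lr_schedule):
            raise ValueError("schedule epoch counts must be positive")

    @property
    def epochs(self) -> int:
        return sum(n for n, _ in self.lr_schedule)


def _encoder_sizes(ng: int, levels: int) -> list[int]:
    return [ng // 2 ** (i + 1) for i in range(levels)]


class Unet3D:
    """A (possibly trained) U-net component model."""

    def __init__(self, config: UnetConfig):
        self.config = config
        in_keys, out_keys, scalar_keys = _CHANNELS[config.component_kind]
        self.in_keys, self.out_keys, self.scalar_keys = (in_keys, out_keys,
                                                         scalar_keys)
        rng = np.random.default_rng(config.seed)
        L, base = config.levels, config.base_filters
        self.filters = [base * 2 ** i for i in range(L)]
        dt = np.float32
        p: list[np.ndarray] = []
        c = len(in_keys)
        for f in self.filters:            # encoder: two convs per level
            p += [he_init(rng, (f, c * 9), c * 9, dt), np.zeros(f, dt)]
            p += [he_init(rng, (f, f * 9), f * 9, dt), np.zeros(f, dt)]
            c = f
        bott = ng_b = config.ng // 2 ** L
        flat = self.filters[-1] * ng_b * ng_b
        ns = len(scalar_keys)
        p += [he_init(rng, (flat, flat + ns), flat + ns, dt),
              np.zeros(flat, dt)]
        c = self.filters[-1]
        for f in reversed(self.filters):  # decoder: convT + conv per level
            p += [he_init(rng, (f, 2, 2, c), 4 * c, dt), np.zeros(f, dt)]
            p += [he_init(rng, (f, 2 * f * 9), 2 * f * 9, dt), np.zeros(f, dt)]
            c = f
        p += [he_init(rng, (len(out_keys), c * 9), c * 9, dt),
              np.zeros(len(out_keys), dt)]
        self.params = p
        self.norm: dict[str, np.ndarray] = {}
        self.loss_history: list[float] = []
        self.lr_history: list[float] = []
        self.trained = False
        from .prep import lumen_mask
        self.mask = lumen_mask(config.ng)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    # ------------------------------------------------------------------
    def _forward(self, x: np.ndarray, scal: np.ndarray):
        """x: (B, Cin, ng, ng) normalized; scal: (B, ns) normalized."""
        p = self.params
        L = self.config.levels
        caches = {"enc": [], "dec": []}
        i = 0
        for lvl in range(L):
            z1, c1 = conv3x3_forward(x, p[i], p[i + 1])
            a1 = relu(z1)
            z2, c2 = conv3x3_forward(a1, p[i + 2], p[i + 3])
            a2 = relu(z2)
            xp, cp = maxpool2_forward(a2)
            caches["enc"].append((c1, z1, c2, z2, a2, cp))
            x = xp
            i += 4
        b_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        cat = np.concatenate([flat, scal.astype(flat.dtype)], axis=1)
        zd = cat @ p[i].T + p[i + 1]
        ad = relu(zd)
        caches["dense"] = (cat, zd, b_shape)
        x = ad.reshape(b_shape)
        i += 2
        for lvl in range(L - 1, -1, -1):
            zt, ct = convT2x2_forward(x, p[i], p[i + 1])
            at = relu(zt)
            skip = caches["enc"][lvl][4]
            catc = np.concatenate([at, skip], axis=1)
            zc, cc = conv3x3_forward(catc, p[i + 2], p[i + 3])
            x = relu(zc)
            caches["dec"].append((ct, zt, cc, zc))
            i += 4
        zo, co = conv3x3_forward(x, p[i], p[i + 1])
        y = zo * self.mask[None, None, :, :]
        caches["out"] = co
        return y, caches

    def _backward(self, dy: np.ndarray, caches):
        p = self.params
        L = self.config.levels
        grads = [None] * len(p)
        i = len(p) - 2
        dy = dy * self.mask[None, None, :, :]
        dx, grads[i], grads[i + 1] = conv3x3_backward(dy, caches["out"])
        dskips = [None] * L
        for lvl in range(L):          # shallowest decoder block first
            i -= 4
            ct, zt, cc, zc = caches["dec"][L - 1 - lvl]
            dz = dx * relu_grad(zc)
            dcat, grads[i + 2], grads[i + 3] = conv3x3_backward(dz, cc)
            f = self.filters[lvl]
            dat, dskips[lvl] = dcat[:, :f], dcat[:, f:]
            dzt = dat * relu_grad(zt)
            dx, grads[i], grads[i + 1] = convT2x2_backward(dzt, ct)
        i -= 2
        cat, zd, b_shape = caches["dense"]
        dad = dx.reshape(dx.shape[0], -1)
        dzd = dad * relu_grad(zd)
        grads[i] = dzd.T @ cat
        grads[i + 1] = dzd.sum(axis=0)
        dcat = dzd @ p[i]
        dx = dcat[:, :np.prod(b_shape[1:])].reshape(b_shape)
        for lvl in range(L - 1, -1, -1):
            i -= 4
            c1, z1, c2, z2, a2, cp = caches["enc"][lvl]
            da2 = maxpool2_backward(dx, cp) + dskips[lvl]
            dz2 = da2 * relu_grad(z2)
            da1, grads[i + 2], grads[i + 3] = conv3x3_backward(dz2, c2)
            dz1 = da1 * relu_grad(z1)
            dx, grads[i], grads[i + 1] = conv3x3_backward(dz1, c1)
        return grads

    # ------------------------------------------------------------------
    def _stack(self, samples, fit_norm: bool):
        cfg = self.config
        xs = np.stack([
            np.stack([s.inputs[k].grid for k in self.in_keys])
            for s in samples]).astype(np.float32)
        ts = np.stack([
            np.stack([s.outputs[k].grid for k in self.out_keys])
            for s in samples]).astype(np.float32)
        sc = np.array([[float(s.scalars[k]) for k in self.scalar_keys]
                       for s in samples], dtype=np.float32)
        if fit_norm and not self.norm:
            scale = np.array(
                [max(np.abs(xs[:, c]).max(), 1e-6)
                 for c in range(xs.shape[1])], dtype=np.float32)
            self.norm = {
                "in_scale": scale,
                "sc_mu": sc.mean(axis=0),
                "sc_sd": np.maximum(sc.std(axis=0), 1e-6).astype(np.float32),
            }
        if not self.norm:
            raise ModelStateError("normalization constants not fitted")
        xs = xs / self.norm["in_scale"][None, :, None, None]
        sc = (sc - self.norm["sc_mu"]) / self.norm["sc_sd"]
        return xs, sc, ts

    def _loss_and_grad(self, y: np.ndarray, t: np.ndarray):
        """Masked combined loss averaged over the batch; gradient w.r.t. y."""
        m = self.mask[None, None, :, :]
        mcount = float(self.mask.sum())
        diff = (y - t) * m
        b = y.shape[0]
        loss = 0.0
        dy = np.zeros_like(y)
        for c, key in enumerate(self.out_keys):
            if key.startswith("u"):
                loss += float(np.sum(diff[:, c] ** 2)) / mcount / b
                dy[:, c] = 2.0 * diff[:, c] / mcount / b
            else:
                tm = np.maximum((t[:, c] * m[:, 0]).reshape(b, -1).max(axis=1)
                                ** 2, 1e-12)
                loss += float(np.sum(
                    diff[:, c] ** 2 / tm[:, None, None])) / mcount / b
                dy[:, c] = 2.0 * diff[:, c] / tm[:, None, None] / mcount / b
        return loss, dy

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "trained": self.trained,
                "loss_history": self.loss_history,
                "lr_history": self.lr_history}
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        arrays.update({f"norm_{k}": v for k, v in self.norm.items()})
        np.savez_compressed(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Unet3D":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfgd = meta["config"]
            cfgd["lr_schedule"] = tuple(map(tuple, cfgd["lr_schedule"]))
            model = cls(UnetConfig(**cfgd))
            model.params = [data[f"p{i}"].copy()
                            for i in range(len(model.params))]
            model.norm = {k[len("norm_"):]: data[k].copy() for k in data.files
                          if k.startswith("norm_")}
            model.loss_history = list(meta["loss_history"])
            model.lr_history = list(meta["lr_history"])
            model.trained = meta["trained"]
        return model


def build_unet(config: UnetConfig, component_kind: str | None = None
               ) -> Unet3D:
    """Build an untrained U-net; ``component_kind`` overrides the config's."""
    if component_kind is not None and component_kind != config.component_kind:
        config = UnetConfig(**{**asdict(config),
                               "component_kind": component_kind})
    return Unet3D(config)


def train_3d(model: Unet3D, samples: list[ComponentSample],
             epochs: int | None = None) -> Unet3D:
    """Train with minibatch Adam under the configured piecewise-constant
    learning-rate schedule; seed-deterministic."""
    if not samples:
        raise ValueError("empty sample list")
    kind = model.config.component_kind
    if any(s.component_kind != kind for s in samples):
        raise ValueError("mixed component kinds in training samples")
    xs, sc, ts = model._stack(samples, fit_norm=True)

    schedule = list(model.config.lr_schedule)
    if epochs is not None:  # proportionally compressed schedule
        total = sum(n for n, _ in schedule)
        compressed = [(max(1, round(n * epochs / total)), lr)
                      for n, lr in schedule]
        extra = epochs - sum(n for n, _ in compressed)
        compressed[-1] = (max(1, compressed[-1][0] + extra),
                          compressed[-1][1])
        schedule = compressed

    rng = np.random.default_rng(model.config.seed + 1)
    opt = Adam(model.params, lr=schedule[0][1])
    bs = model.config.batch_size
    n = len(samples)
    for seg_epochs, lr in schedule:
        opt.lr = lr
        for _ in range(seg_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                sel = order[start:start + bs]
                y, caches = model._forward(xs[sel], sc[sel])
                loss, dy = model._loss_and_grad(y, ts[sel])
                grads = model._backward(dy, caches)
                opt.step(grads)
                epoch_loss += loss * len(sel)
            model.loss_history.append(epoch_loss / n)
            model.lr_history.append(lr)
    model.trained = True
    return model


def predict_component_3d(model: Unet3D,
                         sample: ComponentSample | None = None,
                         inputs: dict | None = None,
                         scalars: dict | None = None) -> dict[str, Field2D]:
    """Deterministic inference; out-of-mask cells are exactly 0 and outputs
    are de-normalized physical fields."""
    if not model.trained:
        raise ModelStateError("model has not been trained")
    if sample is not None:
        inputs, scalars = sample.inputs, sample.scalars
    if inputs is None or scalars is None:
        raise ValueError("either a sample or inputs+scalars must be given")
    for k in model.scalar_keys:
        if k not in scalars:
            raise ValueError(f"missing conditioning scalar {k!r}")
    x = np.stack([inputs[k].grid for k in model.in_keys])[None].astype(
        np.float32)
    x = x / model.norm["in_scale"][None, :, None, None]
    sc = np.array([[float(scalars[k]) for k in model.scalar_keys]],
                  dtype=np.float32)
    sc = (sc - model.norm["sc_mu"]) / model.norm["sc_sd"]
    y, _ = model._forward(x, sc)
    db = float(scalars.get("delta_beta", 0.0))
    out = {}
    for c, key in enumerate(model.out_keys):
        grid = y[0, c].astype(float)
        if key.startswith("H"):
            grid = np.clip(grid, 0.0, 1.0)
            kind = KIND_HEMATOCRIT
        else:
            grid = np.clip(grid, 0.0, None)
            kind = KIND_VELOCITY
        grid[~model.mask] = 0.0
        out[key] = Field2D(grid, model.mask.copy(), db, kind)
    return out


def mae(field_true: Field2D | np.ndarray, field_pred: Field2D | np.ndarray,
        mask: np.ndarray | None = None) -> float:
    """Mean absolute error over in-mask cells, with both fields normalized
    by the true field's in-mask maximum (the comparability convention for
    the dimensionless error)."""
    t = field_true.grid if isinstance(field_true, Field2D) else \
        np.asarray(field_true, dtype=float)
    p = field_pred.grid if isinstance(field_pred, Field2D) else \
        np.asarray(field_pred, dtype=float)
    if mask is None and isinstance(field_true, Field2D):
        mask = field_true.mask
    if mask is None or not np.any(mask):
        raise ValueError("a non-empty mask is required")
    if t.shape != p.shape:
        raise ValueError("field shapes differ")
    scale = float(np.abs(t[mask]).max())
    if scale == 0.0:
        raise ValueError("true field is zero everywhere in the mask")
    return float(np.abs(t[mask] - p[mask]).mean() / scale)
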
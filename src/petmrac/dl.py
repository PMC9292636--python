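"""Slice-wise MR-to-CT translation with a residual dilated CNN.

The architecture follows the high-resolution compact design used for image
regression: a stack of 3x3 convolutions in three dilation blocks (factors 1,
2 and 4), residual connections every two layers, batch normalization and ReLU
inside the residual blocks, and a linear convolutional head.  The full-scale
preset counts 20 convolutional layers (7 / 7 / 6 per block); the desk preset
keeps the topology but narrows the channels so the network trains in minutes
on a single CPU.

The network, batch norm, Adam and backpropagation are implemented directly in
NumPy; convolutions use an im2col formulation with dilation-aware padding so
the output grid always equals the input grid.

CT targets are normalized to [0, 1] via ``(HU + 1000) / 2000`` clipped at
1000 HU (implants saturate); the inverse map is applied at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    n_layers_block1: int = 7
    n_layers_block2: int = 7
    n_layers_block3: int = 6
    dilation_per_block: tuple = (1, 2, 4)
    kernel_size: int = 3
    channels_per_block: tuple = (8, 16, 32)
    residual_every: int = 2

    def validate(self):
        n1, n2, n3 = self.n_layers_block1, self.n_layers_block2, self.n_layers_block3
        if (n1 - 1) % 2 or (n2 - 1) % 2 or (n3 - 2) % 2 or min(n1, n2) < 1 or n3 < 2:
            raise ValueError(
                "block sizes must allow stem/transition convs plus two-layer "
                "residual blocks: need n1, n2 odd and n3 even")
        if self.residual_every != 2:
            raise ValueError("residual connections are defined every two layers")
        return self

    @property
    def total_conv_layers(self):
        return self.n_layers_block1 + self.n_layers_block2 + self.n_layers_block3


def full_network() -> NetworkConfig:
    """Full-width preset: 20 convolutional layers in 7/7/6 dilation blocks."""
    return NetworkConfig(channels_per_block=(16, 32, 64))


def desk_network() -> NetworkConfig:
    """Narrow preset for CPU training on small phantom slices."""
    return NetworkConfig(channels_per_block=(8, 16, 16))


@dataclass
class TrainingConfig:
    loss: str = "l2"
    optimizer: str = "adam"
    lr_start: float = 1e-3
    lr_end: float = 1e-3
    lr_schedule: str = "linear"
    batch_slices: int = 8
    epochs: int = 6
    max_steps: int = 0  # 0 = no cap
    folds: int = 5
    seed: int = 0

    def validate(self):
        if not (self.lr_start >= self.lr_end > 0):
            raise ValueError("require lr_start >= lr_end > 0")
        if self.folds < 2:
            raise ValueError("need at least two cross-validation folds")
        if self.loss != "l2" or self.optimizer != "adam":
            raise ValueError("only the L2 loss with Adam is implemented")
        return self


def full_training() -> TrainingConfig:
    """Full-scale protocol: batch 32 slices, lr decayed linearly 0.04 -> 0.01."""
    return TrainingConfig(lr_start=0.04, lr_end=0.01, batch_slices=32, epochs=50)


def desk_training(epochs: int = 6, seed: int = 0) -> TrainingConfig:
    return TrainingConfig(lr_start=1e-3, lr_end=1e-3, batch_slices=8,
                          epochs=epochs, seed=seed)


HU_CLIP = 1000.0


def hu_to_unit(hu):
    return np.clip((np.asarray(hu, np.float32) + 1000.0) / 2000.0, 0.0, 1.0)


def unit_to_hu(u):
    return np.asarray(u, np.float32) * 2000.0 - 1000.0


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2d:
    """Dilated same-padding convolution on channel-last (N, H, W, C) tensors.

    Implemented as an accumulation of k*k shifted GEMMs, which keeps memory
    traffic low on CPU.
    """

    def __init__(self, cin, cout, kernel, dilation, rng):
        fan_in = cin * kernel * kernel
        self.w = (rng.standard_normal((kernel, kernel, cin, cout))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, np.float32)
        self.kernel = kernel
        self.dilation = dilation
        self.cin, self.cout = cin, cout
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        k, d = self.kernel, self.dilation
        pad = d * (k // 2)
        n, h, w, _ = x.shape
        self._xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        y = np.empty((n, h, w, self.cout), np.float32)
        y[...] = self.b
        for i in range(k):
            for j in range(k):
                y += self._xp[:, i * d:i * d + h, j * d:j * d + w, :] @ self.w[i, j]
        return y

    def backward(self, gy):
        k, d = self.kernel, self.dilation
        pad = d * (k // 2)
        n, h, w, _ = gy.shape
        gxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                xv = self._xp[:, i * d:i * d + h, j * d:j * d + w, :]
                self.gw[i, j] += np.tensordot(xv, gy, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, i * d:i * d + h, j * d:j * d + w, :] += gy @ self.w[i, j].T
        self.gb += gy.sum(axis=(0, 1, 2))
        return gxp[:, pad:pad + h, pad:pad + w, :] if pad else gxp

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, np.float32)
        self.beta = np.zeros(c, np.float32)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, gy):
        self.ggamma += (gy * self._xhat).sum(axis=(0, 1, 2))
        self.gbeta += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma
        if not self._train:
            return gxhat / self._std
        return (gxhat - gxhat.mean(axis=(0, 1, 2), keepdims=True)
                - self._xhat * (gxhat * self._xhat).mean(axis=(0, 1, 2),
                                                         keepdims=True)) / self._std

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask

    def params(self):
        return []


class _Seq:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, gy):
        for lyr in reversed(self.layers):
            gy = lyr.backward(gy)
        return gy

    def params(self):
        return [p for lyr in self.layers for p in lyr.params()]


class ResBlock:
    """Pre-activation residual block: x + Conv(ReLU(BN(Conv(ReLU(BN(x))))))."""

    def __init__(self, c, kernel, dilation, rng):
        self.branch = _Seq([
            BatchNorm2d(c), ReLU(), Conv2d(c, c, kernel, dilation, rng),
            BatchNorm2d(c), ReLU(), Conv2d(c, c, kernel, dilation, rng),
        ])

    def forward(self, x, train):
        return x + self.branch.forward(x, train)

    def backward(self, gy):
        return gy + self.branch.backward(gy)

    def params(self):
        return self.branch.params()


class HighResNet2D:
    """The full residual dilated network; see the module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        d1, d2, d3 = config.dilation_per_block
        c1, c2, c3 = config.channels_per_block
        n1, n2, n3 = (config.n_layers_block1, config.n_layers_block2,
                      config.n_layers_block3)
        units = [Conv2d(1, c1, k, d1, rng)]
        units += [ResBlock(c1, k, d1, rng) for _ in range((n1 - 1) // 2)]
        units += [_Seq([BatchNorm2d(c1), ReLU(), Conv2d(c1, c2, k, d2, rng)])]
        units += [ResBlock(c2, k, d2, rng) for _ in range((n2 - 1) // 2)]
        units += [_Seq([BatchNorm2d(c2), ReLU(), Conv2d(c2, c3, k, d3, rng)])]
        units += [ResBlock(c3, k, d3, rng) for _ in range((n3 - 2) // 2)]
        units += [_Seq([BatchNorm2d(c3), ReLU(), Conv2d(c3, 1, k, d3, rng)])]
        self.units = units

    # -- introspection -----------------------------------------------------
    def conv_layers(self):
        convs = []

        def collect(obj):
            if isinstance(obj, Conv2d):
                convs.append(obj)
            elif isinstance(obj, ResBlock):
                collect(obj.branch)
            elif isinstance(obj, _Seq):
                for lyr in obj.layers:
                    collect(lyr)

        for u in self.units:
            collect(u)
        return convs

    @property
    def n_conv_layers(self):
        return len(self.conv_layers())

    def summary(self):
        return [
            {"layer": i + 1, "cin": c.cin, "cout": c.cout,
             "kernel": c.kernel, "dilation": c.dilation}
            for i, c in enumerate(self.conv_layers())
        ]

    @property
    def n_parameters(self):
        return int(sum(p.size for p, _ in self.parameters()))

    # -- compute -----------------------------------------------------------
    def forward(self, x, train):
        for u in self.units:
            x = u.forward(x, train)
        return x

    def backward(self, gy):
        for u in reversed(self.units):
            gy = u.backward(gy)
        return gy

    def parameters(self):
        return [p for u in self.units for p in u.params()]

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    def predict_slices(self, slices):
        """Eval-mode forward on an (N, H, W) stack; returns (N, H, W)."""
        x = np.asarray(slices, np.float32)[..., None]
        return self.forward(x, train=False)[..., 0]

    # -- persistence (runtime artifacts) -----------------------------------
    def save(self, path, extra_meta=None):
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.parameters())}
        bns = [l for l in self._all_layers() if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        meta = {"config": self.config.__dict__, **(extra_meta or {})}
        np.savez(path, meta=json.dumps(meta, default=list), **arrays)

    def _all_layers(self):
        out = []

        def collect(obj):
            if isinstance(obj, ResBlock):
                collect(obj.branch)
            elif isinstance(obj, _Seq):
                for lyr in obj.layers:
                    collect(lyr)
            else:
                out.append(obj)

        for u in self.units:
            collect(u)
        return out

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfgd = meta["config"]
        for key in ("dilation_per_block", "channels_per_block"):
            cfgd[key] = tuple(cfgd[key])
        model = cls(NetworkConfig(**cfgd), seed=0)
        for i, (p, _) in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        bns = [l for l in model._all_layers() if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
        return model


def build_network(config: NetworkConfig = None, seed: int = 0) -> HighResNet2D:
    return HighResNet2D(config or desk_network(), seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: HighResNet2D, mr_slices, ct_slices, cfg: TrainingConfig):
    """Train on paired (MR, CT-HU) slices; returns ``(model, loss_trace)``.

    CT targets are mapped to [0, 1] internally; the loss trace is the per-step
    L2 loss in normalized units.
    """
    cfg.validate()
    x = np.asarray(mr_slices, np.float32)
    y_hu = np.asarray(ct_slices, np.float32)
    if x.shape != y_hu.shape or x.ndim != 3:
        raise ValueError("paired slices must share an (N, H, W) shape")
    y = hu_to_unit(y_hu).astype(np.float32)

    n = x.shape[0]
    bs = min(cfg.batch_slices, n)
    steps_per_epoch = int(np.ceil(n / bs))
    total = cfg.epochs * steps_per_epoch
    if cfg.max_steps:
        total = min(total, cfg.max_steps)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters())
    trace = []
    step = 0
    while step < total:
        perm = rng.permutation(n)
        for b in range(steps_per_epoch):
            if step >= total:
                break
            idx = perm[b * bs:(b + 1) * bs]
            xb = x[idx][..., None]
            yb = y[idx][..., None]
            pred = model.forward(xb, train=True)
            diff = pred - yb
            loss = float((diff ** 2).mean())
            model.zero_grad()
            model.backward((2.0 * diff / diff.size).astype(np.float32))
            frac = step / max(total - 1, 1)
            lr = cfg.lr_start + (cfg.lr_end - cfg.lr_start) * frac
            opt.step(lr)
            trace.append(loss)
            step += 1
    return model, np.asarray(trace)


def predict_sct(model: HighResNet2D, mr_norm: np.ndarray) -> np.ndarray:
    """Slice-wise inference on a (z, y, x) MR volume; returns HU."""
    out = model.predict_slices(np.asarray(mr_norm, np.float32))
    return unit_to_hu(out).astype(np.float32)


def crossval_split(subject_ids, k: int = 5, seed: int = 0):
    """Subject-level k-fold partition: disjoint, exhaustive validation folds."""
    ids = list(subject_ids)
    if k < 2 or k > len(ids):
        raise ValueError("need 2 <= k <= number of subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = []
    for chunk in np.array_split(order, k):
        val = [ids[i] for i in chunk]
        train_ids = [s for s in ids if s not in val]
        folds.append({"train": train_ids, "val": val})
    return folds


def save_loss_trace(path, trace):
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["step", "l2_loss"])
        for i, v in enumerate(trace):
            w.writerow([i, f"{v:.8g}"])


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class DeepSCT(BaseEstimator):
    """MR->CT translation estimator around the residual dilated CNN."""

    def __init__(self, network: str = "desk", epochs: int = 6,
                 batch_slices: int = 8, lr_start: float = 3e-3,
                 lr_end: float = 1e-3, max_steps: int = 0, seed: int = 0):
        self.network = network
        self.epochs = epochs
        self.batch_slices = batch_slices
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.max_steps = max_steps
        self.seed = seed

    def _network_config(self):
        return {"desk": desk_network, "full": full_network}[self.network]()

    def fit(self, mr_volumes, ct_volumes, y=None):
        """Fit on co-registered (MR, CT) volumes or slice stacks."""
        mr_slices = np.concatenate([np.asarray(v).reshape(-1, *np.asarray(v).shape[-2:])
                                    for v in mr_volumes])
        ct_slices = np.concatenate([np.asarray(v).reshape(-1, *np.asarray(v).shape[-2:])
                                    for v in ct_volumes])
        cfg = TrainingConfig(lr_start=self.lr_start, lr_end=self.lr_end,
                             batch_slices=self.batch_slices, epochs=self.epochs,
                             max_steps=self.max_steps, seed=self.seed)
        model = build_network(self._network_config(), seed=self.seed)
        self.model_, self.loss_trace_ = train(model, mr_slices, ct_slices, cfg)
        return self

    def predict(self, mr_norm):
        return predict_sct(self.model_, mr_norm)
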
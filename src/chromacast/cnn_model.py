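"""A small CNN regressor mapping Gramian-image tensors to log profiles.

Four 3x3 convolution stages (each followed by a rectifier and 2x2 max
pooling) feed two fully-connected layers whose linear output is the
log-relative-concentration profile.  Training minimizes mean absolute
error with RMSProp.  Convolutions run through fused numba kernels
(:mod:`~chromacast._kernels`); the dense layers use BLAS.  Everything is
float32 and seeded, so runs are bit-reproducible on one thread.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from ._kernels import conv3x3_bwd, conv3x3_relu_fwd
from .encoding import Layout

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "split_data",
    "train",
    "predict",
    "param_count",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    The four convolution stages and two dense stages are fixed; their
    sizes are not.  The default channel widths are sized so a 2,000-pair
    training run finishes in minutes on one CPU.
    """

    layout: Layout = Layout.STACKED_5D
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)
    kernel: int = 3
    pool: int = 2
    dense_width: int = 512
    output_len: int = 1501
    lr: float = 1e-3
    lr_decay: float = 0.7      # per-epoch multiplicative learning-rate decay
    rho: float = 0.9           # RMSProp decay
    rms_eps: float = 1e-8
    batch_size: int = 32
    epochs: int = 10
    train_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        self.layout = Layout(self.layout)
        self.conv_channels = tuple(self.conv_channels)
        if len(self.conv_channels) != 4:
            raise ValueError("the architecture has exactly 4 convolution stages")
        if self.kernel != 3 or self.pool != 2:
            raise ValueError("kernels are fixed at 3x3 and pooling at 2x2")

    def input_shape(self) -> tuple[int, int, int]:
        if self.layout is Layout.CONCAT_1D:
            return (640, 128, 1)
        return (128, 128, 5)


@dataclass
class TrainedModel:
    """Weights, config, per-epoch history and the data-split record."""

    config: ModelConfig
    params: list[np.ndarray]
    history: list[dict] = field(default_factory=list)
    split_record: dict = field(default_factory=dict)


def _init_params(config: ModelConfig, rng: np.random.Generator) -> list[np.ndarray]:
    h, w, c = config.input_shape()
    params: list[np.ndarray] = []
    cin = c
    for cout in config.conv_channels:
        fan_in = 9 * cin
        params.append(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (3, 3, cin, cout)).astype(np.float32)
        )
        params.append(np.zeros(cout, dtype=np.float32))
        cin = cout
        h //= 2
        w //= 2
    flat = h * w * cin
    params.append(
        rng.normal(0.0, np.sqrt(2.0 / flat), (flat, config.dense_width)).astype(np.float32)
    )
    params.append(np.zeros(config.dense_width, dtype=np.float32))
    params.append(
        rng.normal(0.0, np.sqrt(1.0 / config.dense_width),
                   (config.dense_width, config.output_len)).astype(np.float32)
    )
    params.append(np.zeros(config.output_len, dtype=np.float32))
    return params


def param_count(config: ModelConfig) -> int:
    """Total trainable parameter count (pure function of the config)."""
    return sum(p.size for p in _init_params(config, np.random.default_rng(0)))


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, h, w, c = x.shape
    xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    return out, x  # keep pre-pool activations to rebuild the argmax mask


def _pool_backward(dout: np.ndarray, x: np.ndarray, out: np.ndarray) -> np.ndarray:
    b, h, w, c = x.shape
    xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
    mask = xr == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    return (mask * (dout[:, :, None, :, None, :] / counts)).reshape(x.shape)


def _forward(params: list[np.ndarray], x: np.ndarray, train_mode: bool):
    caches = []
    a = np.ascontiguousarray(x, dtype=np.float32)
    for stage in range(4):
        w, b = params[2 * stage], params[2 * stage + 1]
        bsz, h, wd, _ = a.shape
        z = np.empty((bsz, h, wd, w.shape[3]), dtype=np.float32)
        conv3x3_relu_fwd(a, w, b, z)
        pooled, prepool = _pool_forward(z)
        if train_mode:
            caches.append((a, prepool, pooled))
        a = pooled
    bsz = a.shape[0]
    flat = a.reshape(bsz, -1)
    w1, b1, w2, b2 = params[8], params[9], params[10], params[11]
    z1 = flat @ w1 + b1
    mask1 = z1 > 0
    h1 = z1 * mask1
    out = h1 @ w2 + b2
    if train_mode:
        caches.append((flat, mask1, h1, a.shape))
    return out, caches


def _backward(params: list[np.ndarray], caches, dout: np.ndarray):
    grads: list[np.ndarray] = [np.zeros_like(p) for p in params]
    flat, mask1, h1, conv_out_shape = caches[-1]
    w1, w2 = params[8], params[10]
    grads[10][:] = h1.T @ dout
    grads[11][:] = dout.sum(axis=0)
    dh1 = ((dout @ w2.T) * mask1).astype(np.float32)
    grads[8][:] = flat.T @ dh1
    grads[9][:] = dh1.sum(axis=0)
    da = (dh1 @ w1.T).reshape(conv_out_shape)
    for stage in range(3, -1, -1):
        a_in, prepool, pooled = caches[stage]
        dz = _pool_backward(da, prepool, pooled)
        # the fwd kernel fused the relu: prepool > 0 is exactly the gate
        dz *= prepool > 0
        dz = np.ascontiguousarray(dz, dtype=np.float32)
        da = np.zeros_like(a_in)
        conv3x3_bwd(a_in, dz, params[2 * stage], da, grads[2 * stage], grads[2 * stage + 1])
    return grads


def split_data(
    pairs: list,
    train_fraction: float = 0.85,
    seed: int = 0,
    group_key=None,
) -> tuple[list, list]:
    """Seeded disjoint/exhaustive split of pairwise records.

    With ``group_key`` (a callable or attribute name, e.g. the plant id),
    all records of one group land on the same side, preventing augmented
    copies of a sample from leaking across the split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    min_side = min(train_fraction, 1 - train_fraction)
    if len(pairs) < int(np.ceil(1.0 / min_side)):
        raise ValueError("too few pairs for the requested split fraction")
    rng = np.random.default_rng(seed)
    if group_key is None:
        idx = rng.permutation(len(pairs))
        cut = int(round(train_fraction * len(pairs)))
        train_idx, test_idx = idx[:cut], idx[cut:]
    else:
        getter = group_key if callable(group_key) else (lambda r, k=group_key: getattr(r, k))
        groups: dict = {}
        for i, rec in enumerate(pairs):
            groups.setdefault(getter(rec), []).append(i)
        keys = sorted(groups, key=str)
        order = rng.permutation(len(keys))
        cut = int(round(train_fraction * len(keys)))
        train_idx = np.array(
            [i for pos in order[:cut] for i in groups[keys[pos]]], dtype=int
        )
        test_idx = np.array(
            [i for pos in order[cut:] for i in groups[keys[pos]]], dtype=int
        )
        if len(test_idx) == 0 or len(train_idx) == 0:
            raise ValueError("grouping left one side of the split empty")
    return [pairs[i] for i in train_idx], [pairs[i] for i in test_idx]


def _stack_batch(pairs: list) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([np.asarray(p.tensor, dtype=np.float32) for p in pairs])
    ys = np.stack([np.asarray(p.target, dtype=np.float32) for p in pairs])
    return xs, ys


def train(
    config: ModelConfig,
    train_pairs: list,
    val_pairs: list | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Run MAE/RMSProp training for the configured number of epochs.

    ``train_pairs`` are records with ``tensor`` (H x W x D float array
    matching the layout) and ``target`` (log-profile vector) attributes.
    Aborts with diagnostics if the loss turns non-finite.
    """
    xs, ys = _stack_batch(train_pairs)
    expected = config.input_shape()
    if xs.shape[1:] != expected:
        raise ValueError(f"tensor shape {xs.shape[1:]} does not match layout {expected}")
    if ys.shape[1] != config.output_len:
        raise ValueError("target length does not match config.output_len")
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    cache_sq = [np.zeros_like(p) for p in params]
    model = TrainedModel(config=config, params=params)
    n = len(train_pairs)
    val = _stack_batch(val_pairs) if val_pairs else None
    for epoch in range(config.epochs):
        t0 = time.time()
        lr = config.lr * config.lr_decay**epoch
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = xs[sel], ys[sel]
            out, caches = _forward(params, xb, train_mode=True)
            diff = out - yb
            loss = float(np.abs(diff).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            epoch_loss += loss * len(sel)
            dout = (np.sign(diff) / diff.size).astype(np.float32)
            grads = _backward(params, caches, dout)
            for p, g, c in zip(params, grads, cache_sq):
                np.multiply(c, config.rho, out=c)
                c += (1.0 - config.rho) * g * g
                p -= lr * g / (np.sqrt(c) + config.rms_eps)
        entry = {"epoch": epoch, "train_mae": epoch_loss / n, "seconds": time.time() - t0}
        if val is not None:
            pred = predict(model, val[0])
            entry["val_mae"] = float(np.abs(pred - val[1]).mean())
        model.history.append(entry)
        if verbose:
            print(json.dumps(entry))
    return model


def predict(model: TrainedModel, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Deterministic inference; accepts one tensor or a batch of them."""
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    expected = model.config.input_shape()
    if x.shape[1:] != expected:
        raise ValueError(f"tensor shape {x.shape[1:]} does not match layout {expected}")
    outs = []
    for start in range(0, len(x), batch_size):
        out, _ = _forward(model.params, x[start : start + batch_size], train_mode=False)
        outs.append(out)
    result = np.concatenate(outs, axis=0)
    return result[0] if single else result


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize weights + config + history to HDF5."""
    with h5py.File(path, "w") as fh:
        cfg = asdict(model.config)
        cfg["layout"] = model.config.layout.value
        fh.attrs["config"] = json.dumps(cfg)
        fh.attrs["history"] = json.dumps(model.history)
        fh.attrs["split_record"] = json.dumps(model.split_record)
        for i, p in enumerate(model.params):
            fh.create_dataset(f"param_{i}", data=p)


def load_model(path: str | Path) -> TrainedModel:
    with h5py.File(path, "r") as fh:
        cfg = json.loads(fh.attrs["config"])
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        config = ModelConfig(**cfg)
        params = [fh[f"param_{i}"][()] for i in range(len(fh.keys()))]
        history = json.loads(fh.attrs["history"])
        split_record = json.loads(fh.attrs["split_record"])
    return TrainedModel(config=config, params=params, history=history, split_record=split_record)
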
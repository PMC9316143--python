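"""The four-branch 3D+2D convolutional disparity network, its training loop,
and full-image inference.

Architecture. Each of the four orientation cuboids (9 × H+8 × W+8 × 3) feeds
its own branch of four 3D convolutions (3×3×3 kernels, VALID padding, stride
1, ReLU) with 32, 64, 64 and 128 feature maps. Each VALID 3×3×3 convolution
removes two from every axis it sees, so the view axis contracts 9→7→5→3→1 and
the 4-px spatial pre-padding is consumed, leaving H × W. The singleton view
axis is squeezed; the 0°/90° branches and the 45°/135° branches are
concatenated pairwise into two streams, each passing seven 2D convolutions
(3×3, SAME) with 128, 64, 32, 32, 16, 8 and 1 channels, ReLU on all but the
last. The two single-channel maps are fused by a 1×1 convolution initialized
to averaging. The network is fully convolutional: any H, W ≥ 1 runs, and a
whole frame is predicted in one pass.

Training minimizes the mean absolute error between predicted and ground-truth
disparity patches with Adam at learning rate 4e-4, decayed by ×0.9 every 100
epochs (a staircase: lr·0.9^floor(epoch/100)), batch size 32.

The convolutions, backpropagation and Adam are implemented directly on numpy
arrays (forward via strided window views contracted with ``np.tensordot``,
backward via the transpose contractions), which keeps the package free of a
deep-learning framework dependency and makes every gradient auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .epi import ORIENTATIONS, CuboidRecord, cuboids_from_stacks, normalize_zero_mean, pad_spatial
from .geometry import StarStacks, select_star_views, calibrate_brightness
from .lightfield import DisparityMap, SceneBundle
from . import metrics as _metrics

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "DepthNet",
    "build_network",
    "train",
    "predict_disparity",
    "predict_from_stacks",
    "predict_from_records",
    "evaluate",
    "lr_at_epoch",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NetworkConfig:
    n_views: int = 9
    in_channels: int = 3
    branch_3d_channels: tuple[int, ...] = (32, 64, 64, 128)
    tail_2d_channels: tuple[int, ...] = (128, 64, 32, 32, 16, 8, 1)
    spatial_pad: int = 4

    def __post_init__(self) -> None:
        n3d = len(self.branch_3d_channels)
        if self.n_views - 2 * n3d != 1:
            raise ValueError(
                f"{n3d} VALID 3x3x3 convolutions contract the view axis "
                f"{self.n_views}->{self.n_views - 2 * n3d}; it must end at exactly 1"
            )
        if 2 * n3d != 2 * self.spatial_pad:
            raise ValueError(
                f"spatial pre-padding {self.spatial_pad} px per side must equal the "
                f"{n3d} VALID convolutions' total spatial shrink of {n3d} px per side"
            )
        if self.tail_2d_channels[-1] != 1:
            raise ValueError("last 2D layer must emit a single channel")

    def scaled(self, factor: float) -> "NetworkConfig":
        """Shrink channel widths by ``factor`` (≥1 channel), e.g. 0.25 to quarter them."""
        b3 = tuple(max(1, int(round(c * factor))) for c in self.branch_3d_channels)
        t2 = tuple(max(1, int(round(c * factor))) for c in self.tail_2d_channels[:-1]) + (1,)
        return replace(self, branch_3d_channels=b3, tail_2d_channels=t2)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 2000
    lr: float = 0.0004
    decay_every: int = 100
    decay_factor: float = 0.9
    seed: int = 0
    loss: str = "mae"


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Staircase schedule: ``lr · decay_factor^floor(epoch / decay_every)``."""
    return cfg.lr * cfg.decay_factor ** (epoch // cfg.decay_every)


# ---------------------------------------------------------------------------
# layers


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class _Conv3dValid:
    """3×3×3 convolution, VALID padding, stride 1, on (N, V, H, W, C) tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = 27 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (3, 3, 3, c_in, c_out))
        self.w = _Param(w)
        self.b = _Param(np.zeros(c_out))
        self._win = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        win = sliding_window_view(x, (3, 3, 3), axis=(1, 2, 3))  # (n,v',h',w',c,3,3,3)
        self._win = win
        out = np.tensordot(win, self.w.value, axes=([5, 6, 7, 4], [0, 1, 2, 3]))
        out += self.b.value
        self._in_shape = x.shape
        self._dtype = x.dtype
        return out.astype(self._dtype, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.b.grad += gout.sum(axis=(0, 1, 2, 3))
        # (n,v',h',w',c,i,j,k) x (n,v',h',w',o) -> (c,i,j,k,o)
        dw = np.tensordot(self._win, gout, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.w.grad += dw.transpose(1, 2, 3, 0, 4)
        dx = np.zeros(self._in_shape, dtype=self._dtype)
        vo, ho, wo = gout.shape[1:4]
        W = self.w.value
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    dx[:, i:i + vo, j:j + ho, k:k + wo, :] += gout @ W[i, j, k].T
        self._win = None
        return dx


class _Conv2dSame:
    """k×k convolution, SAME (zero) padding, on (N, H, W, C) tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, ksize: int = 3,
                 init: np.ndarray | None = None):
        if init is not None:
            w = init
        else:
            fan_in = ksize * ksize * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (ksize, ksize, c_in, c_out))
        self.w = _Param(np.asarray(w, dtype=np.float32))
        self.b = _Param(np.zeros(c_out))
        self.ksize = ksize
        self._win = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.ksize // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = sliding_window_view(xp, (self.ksize, self.ksize), axis=(1, 2))  # (n,h,w,c,k,k)
        self._win = win
        self._xp_shape = xp.shape
        out = np.tensordot(win, self.w.value, axes=([4, 5, 3], [0, 1, 2]))
        out += self.b.value
        self._dtype = x.dtype
        return out.astype(self._dtype, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.b.grad += gout.sum(axis=(0, 1, 2))
        dw = np.tensordot(self._win, gout, axes=([0, 1, 2], [0, 1, 2]))  # (c,k,k,o)
        self.w.grad += dw.transpose(1, 2, 0, 3)
        dxp = np.zeros(self._xp_shape, dtype=self._dtype)
        ho, wo = gout.shape[1:3]
        W = self.w.value
        for i in range(self.ksize):
            for j in range(self.ksize):
                dxp[:, i:i + ho, j:j + wo, :] += gout @ W[i, j].T
        p = self.ksize // 2
        self._win = None
        return dxp[:, p:dxp.shape[1] - p, p:dxp.shape[2] - p, :] if p else dxp


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gout, 0.0)
        self._mask = None
        return g


# ---------------------------------------------------------------------------
# the model


class DepthNet:
    """Four 3D-conv branches, two 2D-conv streams, averaged-init 1×1 fusion."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.branches = {o: self._make_branch(rng) for o in ORIENTATIONS}
        c_last = cfg.branch_3d_channels[-1]
        self.streams = {
            "0_90": self._make_stream(2 * c_last, rng),
            "45_135": self._make_stream(2 * c_last, rng),
        }
        # fusion: 1x1 conv over the two single-channel maps, initialized to averaging
        self.fusion = _Conv2dSame(2, 1, rng, ksize=1,
                                  init=np.full((1, 1, 2, 1), 0.5))

    def _make_branch(self, rng):
        layers = []
        c_in = self.cfg.in_channels
        for c_out in self.cfg.branch_3d_channels:
            layers.append(_Conv3dValid(c_in, c_out, rng))
            layers.append(_ReLU())
            c_in = c_out
        return layers

    def _make_stream(self, c_in, rng):
        layers = []
        chans = self.cfg.tail_2d_channels
        for li, c_out in enumerate(chans):
            layers.append(_Conv2dSame(c_in, c_out, rng))
            if li < len(chans) - 1:  # no activation on the last 2D layer
                layers.append(_ReLU())
            c_in = c_out
        return layers

    def params(self):
        ps = []
        for o in ORIENTATIONS:
            for layer in self.branches[o]:
                ps.extend(layer.params())
        for s in self.streams.values():
            for layer in s:
                ps.extend(layer.params())
        ps.extend(self.fusion.params())
        return ps

    # forward / backward ----------------------------------------------------

    def forward(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        """inputs: orientation -> (N, n_views, H+2p, W+2p, C); returns (N, H, W)."""
        feats = {}
        for o in ORIENTATIONS:
            x = np.ascontiguousarray(inputs[o])
            if x.shape[1] != self.cfg.n_views:
                raise ValueError(
                    f"orientation {o}: expected {self.cfg.n_views} views, got {x.shape[1]}"
                )
            for layer in self.branches[o]:
                x = layer.forward(x)
            if x.shape[1] != 1:
                raise AssertionError("view axis did not contract to 1")
            feats[o] = x[:, 0]  # squeeze the singleton view axis
        self._feat_shapes = {o: feats[o].shape for o in ORIENTATIONS}
        sa = np.concatenate([feats["0"], feats["90"]], axis=-1)
        sb = np.concatenate([feats["45"], feats["135"]], axis=-1)
        for layer in self.streams["0_90"]:
            sa = layer.forward(sa)
        for layer in self.streams["45_135"]:
            sb = layer.forward(sb)
        fused = self.fusion.forward(np.concatenate([sa, sb], axis=-1))
        return fused[..., 0]

    def backward(self, gout: np.ndarray) -> None:
        g = self.fusion.backward(gout[..., None])
        ga, gb = g[..., :1], g[..., 1:]
        for layer in reversed(self.streams["0_90"]):
            ga = layer.backward(ga)
        for layer in reversed(self.streams["45_135"]):
            gb = layer.backward(gb)
        c = self._feat_shapes["0"][-1]
        grads = {"0": ga[..., :c], "90": ga[..., c:], "45": gb[..., :c], "135": gb[..., c:]}
        for o in ORIENTATIONS:
            gx = grads[o][:, None]  # restore the singleton view axis
            for layer in reversed(self.branches[o]):
                gx = layer.backward(gx)

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # persistence -----------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{k}": p.value for k, p in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        ps = self.params()
        if len(arrays) != len(ps):
            raise ValueError(f"checkpoint has {len(arrays)} tensors; model needs {len(ps)}")
        for k, p in enumerate(ps):
            a = arrays[f"p{k}"]
            if a.shape != p.value.shape:
                raise ValueError(f"checkpoint tensor p{k} shape {a.shape} != {p.value.shape}")
            p.value = a.astype(np.float32)


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> DepthNet:
    return DepthNet(cfg or NetworkConfig(), seed=seed)


def save_model(model: DepthNet, path: str | Path) -> None:
    """Checkpoint as an .npz plus the architecture config in the archive."""
    cfg = model.cfg
    np.savez(
        path,
        __cfg_n_views=cfg.n_views,
        __cfg_in_channels=cfg.in_channels,
        __cfg_branch=np.array(cfg.branch_3d_channels),
        __cfg_tail=np.array(cfg.tail_2d_channels),
        __cfg_pad=cfg.spatial_pad,
        **model.state_arrays(),
    )


def load_model(path: str | Path) -> DepthNet:
    with np.load(path) as z:
        cfg = NetworkConfig(
            n_views=int(z["__cfg_n_views"]),
            in_channels=int(z["__cfg_in_channels"]),
            branch_3d_channels=tuple(int(c) for c in z["__cfg_branch"]),
            tail_2d_channels=tuple(int(c) for c in z["__cfg_tail"]),
            spatial_pad=int(z["__cfg_pad"]),
        )
        model = DepthNet(cfg)
        model.load_state_arrays({k: z[k] for k in z.files if not k.startswith("__cfg")})
    return model


# ---------------------------------------------------------------------------
# training


def _records_to_batch(records: list[CuboidRecord], pad: int) -> tuple[dict, np.ndarray]:
    inputs = {
        o: np.stack([
            pad_spatial(normalize_zero_mean(r.cuboids[o]), pad).data for r in records
        ])
        for o in ORIENTATIONS
    }
    gt = np.stack([r.gt for r in records])
    return inputs, gt


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad ** 2
            p.value -= lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)


def train(
    model: DepthNet,
    records: list[CuboidRecord] | str | Path,
    cfg: TrainConfig,
    val_records: list[CuboidRecord] | None = None,
    log_every: int = 0,
) -> list[dict]:
    """Minimize the MAE loss over ground-truth patches; returns the loss history.

    One epoch is one shuffled pass over the records. Batch order and any
    remaining randomness derive from ``cfg.seed``. Aborts on a non-finite loss.
    """
    if isinstance(records, (str, Path)):
        from .epi import read_cuboids
        records = read_cuboids(records)
    if not records:
        raise ValueError("empty training dataset")
    if any(r.gt is None for r in records):
        raise ValueError("training records must carry ground-truth patches")
    if cfg.loss != "mae":
        raise ValueError(f"unsupported loss {cfg.loss!r}")

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params())
    pad = model.cfg.spatial_pad
    history = []
    n = len(records)
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        epoch_abs = 0.0
        epoch_count = 0
        for start in range(0, n, cfg.batch_size):
            batch = [records[k] for k in order[start:start + cfg.batch_size]]
            inputs, gt = _records_to_batch(batch, pad)
            pred = model.forward(inputs)
            # error in float64 so the reported MAE matches the metrics module
            err = pred.astype(np.float64) - gt.astype(np.float64)
            loss = float(np.abs(err).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lr={lr}, batch start {start}"
                )
            epoch_abs += float(np.abs(err).sum())
            epoch_count += err.size
            model.zero_grad()
            model.backward(np.sign(err).astype(np.float32) / err.size)
            opt.step(lr)
        entry = {"epoch": epoch, "lr": lr, "train_mae": epoch_abs / epoch_count}
        if val_records:
            entry["val_mae"] = _dataset_mae(model, val_records, cfg.batch_size)
        history.append(entry)
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d lr %.2e train MAE %.4f %s", epoch, lr, entry["train_mae"],
                        f"val MAE {entry['val_mae']:.4f}" if "val_mae" in entry else "")
    return history


def _dataset_mae(model: DepthNet, records: list[CuboidRecord], batch_size: int) -> float:
    total, count = 0.0, 0
    pad = model.cfg.spatial_pad
    for start in range(0, len(records), batch_size):
        inputs, gt = _records_to_batch(records[start:start + batch_size], pad)
        pred = model.forward(inputs)
        total += float(np.abs(pred.astype(np.float64) - gt).sum())
        count += gt.size
    return total / count


# ---------------------------------------------------------------------------
# inference and evaluation


def predict_from_stacks(model: DepthNet, stacks: StarStacks) -> DisparityMap:
    """Full-frame inference: normalize per cuboid, pad, one forward pass."""
    cubs = cuboids_from_stacks(stacks, n_views=model.cfg.n_views)
    shapes = {c.data.shape for c in cubs.values()}
    if len(shapes) != 1:
        raise ValueError(f"view shape mismatch among star stacks: {shapes}")
    pad = model.cfg.spatial_pad
    inputs = {
        o: pad_spatial(normalize_zero_mean(cubs[o]), pad).data[None] for o in ORIENTATIONS
    }
    pred = model.forward(inputs)[0]
    return DisparityMap(pred.astype(np.float32))


def predict_disparity(
    model: DepthNet,
    scene: SceneBundle | StarStacks,
    interval: int = 1,
    calibrate: bool = False,
) -> DisparityMap:
    """Predict a full-frame disparity map for a scene (or prepared star stacks)."""
    if isinstance(scene, StarStacks):
        stacks = scene
    else:
        stacks = select_star_views(scene.lightfield, n_views=model.cfg.n_views,
                                   interval=interval)
        if calibrate:
            stacks = calibrate_brightness(stacks)
    return predict_from_stacks(model, stacks)


def predict_from_records(model: DepthNet, records: list[CuboidRecord],
                         batch_size: int = 32) -> np.ndarray:
    """Predict per-record patches; returns (n_records, h, w)."""
    pad = model.cfg.spatial_pad
    out = []
    for start in range(0, len(records), batch_size):
        batch = records[start:start + batch_size]
        inputs = {
            o: np.stack([
                pad_spatial(normalize_zero_mean(r.cuboids[o]), pad).data for r in batch
            ])
            for o in ORIENTATIONS
        }
        out.append(model.forward(inputs))
    return np.concatenate(out)


def evaluate(model: DepthNet, scenes: list[SceneBundle], interval: int = 1) -> list[dict]:
    """Per-scene MAE and RMSE against ground truth; scenes without gt are skipped."""
    rows = []
    for scene in scenes:
        if scene.gt_disparity is None:
            logger.warning("scene %s has no ground truth; skipped", scene.name)
            continue
        pred = predict_disparity(model, scene, interval=interval)
        rows.append({
            "scene": scene.name,
            "mae": _metrics.mae(pred.values, scene.gt_disparity.values),
            "rmse": _metrics.rmse(pred.values, scene.gt_disparity.values),
        })
    if rows:
        rows.append({
            "scene": "mean",
            "mae": float(np.mean([r["mae"] for r in rows])),
            "rmse": float(np.mean([r["rmse"] for r in rows])),
        })
    return rows
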
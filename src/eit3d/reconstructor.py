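"""Learned absolute reconstruction: 45 x 48 feature map -> element conductivity.

The regression network is a bottleneck residual CNN (see ``eit3d.nn``).
Training minimises an amplified mean-squared error ``alpha * MSE`` — the
raw per-element conductivity residuals are small, and the amplification
raises the gradient signal so the regression head converges; ``alpha = 1``
recovers plain MSE. Inputs are standardised per feature-map position and
targets per element with training-split statistics (see ``TrainedModel``);
the statistics travel with the checkpoint and are inverted at predict time.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .dataset import SampleSet
from .fem import ConductivityField
from .mesh import Mesh
from .nn import Adam, BottleneckRegressor, ReduceLROnPlateau
from .protocol import FeatureMap, FRAME_LEN, VoltageFrame, frame_to_featuremap


@dataclass(frozen=True)
class NetworkSpec:
    output_dim: int
    input_shape: tuple[int, int, int] = (1, 45, 48)
    stem_channels: int = 64
    stage_depths: tuple[int, ...] = (3, 4, 6, 3)
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    bottleneck_expansion: int = 4

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if len(self.stage_depths) != len(self.stage_widths):
            raise ValueError("stage_depths and stage_widths must have equal length")

    @property
    def pooled_dim(self) -> int:
        return self.stage_widths[-1] * self.bottleneck_expansion

    @classmethod
    def reduced(cls, output_dim: int) -> "NetworkSpec":
        """Desk-scale configuration for single-CPU experiments."""
        return cls(output_dim=output_dim, stem_channels=16,
                   stage_depths=(2, 2, 2, 2), stage_widths=(16, 32, 64, 128))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    base_lr: float = 1e-4
    alpha: float = 100.0  # loss amplification factor
    lr_factor: float = 0.5
    lr_patience: int = 5
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.base_lr <= 0 or self.alpha <= 0:
            raise ValueError("base_lr and alpha must be positive")


def build_network(spec: NetworkSpec, seed: int = 0) -> BottleneckRegressor:
    """Instantiate an untrained bottleneck regression network."""
    return BottleneckRegressor(
        output_dim=spec.output_dim,
        stage_depths=spec.stage_depths,
        stage_widths=spec.stage_widths,
        stem_channels=spec.stem_channels,
        seed=seed,
    )


def amplified_loss(pred, target, alpha: float = 100.0) -> float:
    """alpha * mean squared error; alpha = 1 reduces to plain MSE."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(alpha * np.mean((pred - target) ** 2))


@dataclass
class TrainedModel:
    """A trained network plus the normalization statistics it was fitted with.

    Inputs are standardized per feature-map position (each of the 45 x 48
    measurement positions is z-scored with training-split statistics: the
    positions span decades of scale, and a global scaling drowns the small
    informative variations). Targets are standardized per element with a
    shrunk standard deviation (std + 5% of the largest element std), which
    balances the loss across elements without exploding near-constant ones;
    both transforms are inverted at predict time.
    """

    spec: NetworkSpec
    network: BottleneckRegressor
    feat_mean: np.ndarray  # (45, 48)
    feat_std: np.ndarray  # (45, 48)
    target_center: np.ndarray  # (N,)
    target_scale: np.ndarray  # (N,)
    history: list = field(default_factory=list)  # (epoch, train_loss, val_loss, lr)
    manifest: dict = field(default_factory=dict)

    def normalize_input(self, maps: np.ndarray) -> np.ndarray:
        return (maps - self.feat_mean) / self.feat_std

    def denormalize_output(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_scale + self.target_center

    def predict_array(self, maps: np.ndarray) -> np.ndarray:
        x = self.normalize_input(np.asarray(maps, dtype=np.float32))
        if x.ndim == 2:
            x = x[None]
        out = self.network.forward(x[:, None], train=False)
        return self.denormalize_output(out.astype(float))


def _frames_to_maps(frames: np.ndarray) -> np.ndarray:
    maps = np.empty((frames.shape[0], 45, 48), dtype=np.float32)
    for i, row in enumerate(frames):
        maps[i] = frame_to_featuremap(VoltageFrame(row)).matrix
    return maps


def train(
    network: BottleneckRegressor,
    sset: SampleSet,
    config: TrainConfig,
    spec: NetworkSpec | None = None,
    use_noisy: bool = True,
    log=None,
) -> TrainedModel:
    """Optimize the amplified loss over the training split; deterministic under seed."""
    tr = sset.train_indices
    va = sset.val_indices
    if tr.size == 0:
        raise ValueError("empty training split")
    frames = sset.frames_noisy if use_noisy else sset.frames_clean
    maps = _frames_to_maps(frames)
    targets = sset.sigma.astype(np.float32)

    feat_mean = maps[tr].mean(axis=0)
    feat_std = maps[tr].std(axis=0) + 1e-12
    t_center = targets[tr].mean(axis=0)
    t_std = targets[tr].std(axis=0)
    t_scale = t_std + 0.05 * max(float(t_std.max()), 1e-30)
    X = ((maps - feat_mean) / feat_std).astype(np.float32)
    Y = ((targets - t_center) / t_scale).astype(np.float32)
    network.fc.b[...] = 0.0  # targets are centered; start at the mean field

    model = TrainedModel(
        spec=spec if spec is not None else NetworkSpec(output_dim=network.output_dim),
        network=network,
        feat_mean=feat_mean,
        feat_std=feat_std,
        target_center=t_center,
        target_scale=t_scale,
        manifest={
            "mesh_hash": sset.manifest.get("mesh_hash"),
            "protocol_hash": sset.manifest.get("protocol_hash"),
            "config": json.dumps(config.__dict__, default=str),
        },
    )

    opt = Adam(network.params(), lr=config.base_lr, weight_decay=config.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=config.lr_factor, patience=config.lr_patience)
    rng = np.random.default_rng(config.seed)
    alpha = config.alpha
    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx][:, None]
            yb = Y[idx]
            pred = network.forward(xb, train=True)
            diff = pred - yb
            loss = alpha * float((diff.astype(np.float64) ** 2).mean())
            grad = (2.0 * alpha / diff.size) * diff
            network.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        val_loss = _eval_loss(network, X, Y, va, alpha, config.batch_size) if va.size else train_loss
        sched.step(val_loss)
        model.history.append((epoch, train_loss, val_loss, opt.lr))
        if log is not None:
            log(f"epoch={epoch} train_loss={train_loss:.6g} val_loss={val_loss:.6g} lr={opt.lr:.3g}")
        if not np.isfinite(train_loss):
            raise RuntimeError(f"training diverged at epoch {epoch}")
    return model


def _eval_loss(network, X, Y, idx, alpha, batch_size) -> float:
    losses = []
    for start in range(0, idx.size, batch_size):
        i = idx[start : start + batch_size]
        pred = network.forward(X[i][:, None], train=False)
        losses.append(alpha * float(((pred - Y[i]).astype(np.float64) ** 2).mean()))
    return float(np.mean(losses))


def predict(model: TrainedModel, fmap: FeatureMap, mesh: Mesh | None = None) -> ConductivityField:
    """Reconstruct a per-element conductivity field from one feature map."""
    if mesh is not None and model.manifest.get("mesh_hash") not in (None, mesh.mesh_hash):
        raise ValueError("model manifest is bound to a different mesh")
    out = model.predict_array(fmap.matrix)[0]
    out = np.clip(out, 1e-10, None)  # fields are physically positive
    return ConductivityField(out, model.manifest.get("mesh_hash") or "")


def save_model(model: TrainedModel, path) -> None:
    state = model.network.state_dict()
    meta = {
        "spec": model.spec.__dict__,
        "history": model.history,
        "manifest": model.manifest,
        "format_version": 1,
    }
    np.savez_compressed(
        path,
        __meta__=json.dumps(meta, default=list),
        __feat_mean__=model.feat_mean,
        __feat_std__=model.feat_std,
        __target_center__=model.target_center,
        __target_scale__=model.target_scale,
        **state,
    )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        spec_d = meta["spec"]
        spec = NetworkSpec(
            output_dim=spec_d["output_dim"],
            input_shape=tuple(spec_d["input_shape"]),
            stem_channels=spec_d["stem_channels"],
            stage_depths=tuple(spec_d["stage_depths"]),
            stage_widths=tuple(spec_d["stage_widths"]),
            bottleneck_expansion=spec_d["bottleneck_expansion"],
        )
        net = build_network(spec)
        reserved = {"__meta__", "__feat_mean__", "__feat_std__",
                    "__target_center__", "__target_scale__"}
        net.load_state_dict({k: data[k] for k in data.files if k not in reserved})
        feat_mean = data["__feat_mean__"]
        feat_std = data["__feat_std__"]
        t_center = data["__target_center__"]
        t_scale = data["__target_scale__"]
    return TrainedModel(
        spec=spec,
        network=net,
        feat_mean=feat_mean,
        feat_std=feat_std,
        target_center=t_center,
        target_scale=t_scale,
        history=[tuple(h) for h in meta["history"]],
        manifest=meta["manifest"],
    )
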
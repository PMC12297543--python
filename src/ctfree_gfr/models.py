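"""The two volumetric networks and their training protocol.

Two 3D U-Nets: a u-map generator mapping the primary-emission and scatter
SPECT windows to a synthetic attenuation map, and a kidney segmenter mapping a
(normalized) attenuation map to per-voxel class probabilities over
{background, right kidney, left kidney}.  Training uses Adam with per-epoch
exponential learning-rate decay (0.96), random flip augmentation along the x
and z axes (an x flip swaps the right/left kidney labels in 3-class targets),
an 8:1:1 train/validation/test split, and patience-based early stopping on the
validation loss.

The clinical-scale profile (64 initial neurons, depth 4, 100 epochs, batch 8)
is available through :meth:`NetworkConfig.paper_scale` /
:meth:`TrainConfig.paper_scale`; the dataclass defaults are a small CPU
profile that trains in minutes on phantom cases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Tensor, UNet3D
from .preprocess import NormalizationSpec, butterworth_lowpass, normalize
from .volume import LEFT_KIDNEY, RIGHT_KIDNEY, LabelMap, Volume3D

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "ProbabilityMap",
    "TrainedModel",
    "build_network",
    "train",
    "predict_mumap",
    "predict_labels",
    "make_segmentation_dataset",
    "make_mumap_dataset",
    "split_indices",
    "ablation_grid",
    "run_ablation_smoke",
    "save_model",
    "load_model",
]

_EPS = 1e-7


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description for either task.

    Defaults are the small CPU profile (8 initial neurons, depth 2); the
    clinical-scale architecture is 64 initial neurons with 4 skip-connection
    levels.
    """

    task: str = "segmentation"          # or "mumap_generation"
    initial_neurons: int = 8
    depth: int = 2
    block: str = "residual"             # or "conventional"
    attention: bool = True
    attention_edge_features: bool = True
    norm_layer: str = "instance"
    upsampling: str = "nearest_neighbor"
    in_channels: int = 1
    out_channels: int = 3
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.task not in ("segmentation", "mumap_generation"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.block not in ("residual", "conventional"):
            raise ValueError(f"unknown block {self.block!r}")
        if self.norm_layer != "instance":
            raise NotImplementedError("only instance normalization is implemented")
        if self.upsampling != "nearest_neighbor":
            raise NotImplementedError("only nearest-neighbor upsampling is implemented")
        if self.task == "segmentation":
            if self.n_classes not in (2, 3):
                raise ValueError("n_classes must be 2 or 3")
            if self.out_channels != self.n_classes:
                raise ValueError("out_channels must equal n_classes for segmentation")

    @classmethod
    def for_segmentation(cls, n_classes: int = 3, **overrides) -> "NetworkConfig":
        return cls(task="segmentation", in_channels=1, out_channels=n_classes,
                   n_classes=n_classes, **overrides)

    @classmethod
    def for_mumap(cls, in_channels: int = 2, **overrides) -> "NetworkConfig":
        return cls(task="mumap_generation", in_channels=in_channels,
                   out_channels=1, n_classes=3, **overrides)

    @classmethod
    def paper_scale(cls, task: str = "segmentation", **overrides) -> "NetworkConfig":
        base = dict(initial_neurons=64, depth=4)
        base.update(overrides)
        if task == "segmentation":
            return cls.for_segmentation(**base)
        return cls.for_mumap(**base)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    Clinical-scale values: 100 epochs, batch 8.  The learning rate decays as
    ``learning_rate * lr_decay**epoch``; early stopping watches the validation
    loss with the given patience.  ``loss`` is CCE/GDSC for segmentation and
    MAE/MSE for u-map regression.
    """

    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    lr_decay: float = 0.96
    early_stopping_patience: int = 10
    augment_flip_axes: tuple[str, ...] = ("x", "z")
    seed: int = 0
    loss: str = "GDSC"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stopping_patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")
        if self.loss not in ("CCE", "GDSC", "MAE", "MSE"):
            raise ValueError(f"unknown loss {self.loss!r}")
        for ax in self.augment_flip_axes:
            if ax not in ("x", "z"):
                raise ValueError(f"flip augmentation axis must be x or z, got {ax!r}")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        base = dict(epochs=10, batch_size=4)
        base.update(overrides)
        base.setdefault("early_stopping_patience", min(10, base["epochs"]))
        return cls(**base)


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities, channel-first, with grid metadata."""

    data: np.ndarray  # (n_classes, D, H, W), sums to 1 over axis 0
    spacing_mm: tuple[float, float, float]

    @property
    def n_classes(self) -> int:
        return self.data.shape[0]

    def argmax_labels(self) -> LabelMap:
        """Hard labels; ties break toward the lowest class index (background)."""
        return LabelMap(np.argmax(self.data, axis=0).astype(np.int16), self.spacing_mm)


@dataclass
class TrainedModel:
    """A trained network plus everything needed to apply it consistently."""

    network: UNet3D
    network_config: NetworkConfig
    train_config: TrainConfig
    normalization: NormalizationSpec
    history: dict
    best_epoch: int
    test_indices: list[int] = field(default_factory=list)


def build_network(config: NetworkConfig, seed: int = 0) -> UNet3D:
    """Instantiate the U-Net described by ``config`` with seeded init."""
    rng = np.random.default_rng(seed)
    head = "softmax" if config.task == "segmentation" else "softplus"
    return UNet3D(
        in_channels=config.in_channels,
        out_channels=config.out_channels,
        initial_neurons=config.initial_neurons,
        depth=config.depth,
        residual=config.block == "residual",
        attention=config.attention,
        head=head,
        rng=rng,
        norm=config.norm_layer,
        attention_edge_features=config.attention_edge_features,
    )


# -- dataset construction ------------------------------------------------------


def make_segmentation_dataset(cases, norm_spec: NormalizationSpec,
                              n_classes: int = 3):
    """(normalized u-map, label array) pairs from phantom cases.

    2-class targets collapse both kidneys into a single foreground class.
    """
    data = []
    for case in cases:
        x = normalize(case.mu_map, norm_spec).data.astype(np.float32)[None]
        lab = case.labels.data.astype(np.int64)
        if n_classes == 2:
            lab = (lab > 0).astype(np.int64)
        data.append((x, lab))
    return data


def make_mumap_dataset(cases, filter_scatter: bool = True):
    """(two-window SPECT input, attenuation-map target) pairs.

    The scatter window is Butterworth low-pass filtered for noise reduction;
    both windows are log-maximum normalized.
    """
    log_max = NormalizationSpec(method="log_maximum")
    data = []
    for case in cases:
        scat = case.scatter_spect
        if filter_scatter:
            scat = butterworth_lowpass(scat)
            scat = scat.with_data(np.clip(scat.data, 0, None))
        prim = normalize(case.primary_spect, log_max).data
        scat_n = normalize(scat, log_max).data
        x = np.stack([prim, scat_n]).astype(np.float32)
        y = case.mu_map.data.astype(np.float32)[None]
        data.append((x, y))
    return data


def split_indices(n: int, seed: int) -> tuple[list[int], list[int], list[int]]:
    """Deterministic 8:1:1 train/validation/test split."""
    order = np.random.default_rng(seed).permutation(n)
    n_val = max(1, round(0.1 * n)) if n >= 3 else 0
    n_test = max(1, round(0.1 * n)) if n >= 3 else 0
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError(f"dataset of {n} cases is too small to split")
    return (
        [int(i) for i in order[:n_train]],
        [int(i) for i in order[n_train:n_train + n_val]],
        [int(i) for i in order[n_train + n_val:]],
    )


# -- losses on graph tensors ---------------------------------------------------


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.moveaxis(np.eye(n_classes, dtype=np.float32)[labels], -1, 1)


def _graph_cce(y: np.ndarray, p: Tensor) -> Tensor:
    n_classes = y.shape[1]
    n_vox = y.size / n_classes
    pc = p.clip(_EPS, 1.0 - _EPS)
    term = pc.log() * y + pc.log1p_neg() * (1.0 - y)
    return -term.sum() * (1.0 / (n_classes * n_vox))


def _graph_gdsc(y: np.ndarray, p: Tensor) -> Tensor:
    vol = y.sum(axis=(0, 2, 3, 4))
    w = (1.0 / (vol**2 + 1e-6)).astype(np.float32)
    inter = (p * y).sum(axis=(0, 2, 3, 4))
    psum = p.sum(axis=(0, 2, 3, 4))
    num = (inter * w).sum()
    den = float((w * vol).sum()) + (psum * w).sum()
    return 1.0 - (num * 2.0) / den


def _graph_regression(y: np.ndarray, p: Tensor, kind: str) -> Tensor:
    diff = p - y
    return diff.abs().mean() if kind == "MAE" else (diff * diff).mean()


def _loss_tensor(loss: str, target: np.ndarray, pred: Tensor,
                 n_classes: int) -> Tensor:
    if loss == "CCE":
        return _graph_cce(_one_hot(target, n_classes), pred)
    if loss == "GDSC":
        return _graph_gdsc(_one_hot(target, n_classes), pred)
    return _graph_regression(target, pred, loss)


# -- training ------------------------------------------------------------------


def _augment_batch(xs, ys, axes, swap_lr: bool, rng) -> tuple:
    """Random flips along the left-right (x) and axial (z) array axes.

    A left-right flip mirrors anatomy, so 3-class segmentation targets swap
    the right/left kidney labels; z flips keep labels.
    """
    xs, ys = xs.copy(), ys.copy()
    for i in range(xs.shape[0]):
        if "x" in axes and rng.random() < 0.5:
            xs[i] = xs[i, :, :, :, ::-1].copy()
            ys[i] = ys[i, ..., ::-1].copy()
            if swap_lr:
                lab = ys[i]
                r, l = lab == RIGHT_KIDNEY, lab == LEFT_KIDNEY
                lab[r], lab[l] = LEFT_KIDNEY, RIGHT_KIDNEY
        if "z" in axes and rng.random() < 0.5:
            xs[i] = xs[i, :, ::-1].copy()
            ys[i] = (ys[i, ::-1] if ys[i].ndim == 3 else ys[i][:, ::-1]).copy()
    return xs, ys


def train(network: UNet3D, dataset, config: TrainConfig,
          normalization: NormalizationSpec | None = None,
          network_config: NetworkConfig | None = None,
          verbose: bool = False) -> TrainedModel:
    """Train on an 8:1:1 split of ``dataset``; return the best-validation model.

    ``dataset`` is a sequence of ``(input, target)`` pairs: channel-first
    float inputs with integer label targets for segmentation, or channel-first
    regression targets for u-map generation.  Deterministic under
    ``config.seed``.  Raises on an empty dataset and aborts with a diagnostic
    if the loss goes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    seg = network.head == "softmax"
    n_classes = network_config.n_classes if network_config else (
        dataset[0][1].max() + 1 if seg else 0
    )
    loss_kind = config.loss
    if seg and loss_kind in ("MAE", "MSE"):
        raise ValueError("segmentation requires a CCE or GDSC loss")
    if not seg and loss_kind in ("CCE", "GDSC"):
        loss_kind = "MAE"

    tr_idx, va_idx, _te_idx = split_indices(len(dataset), config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(network.parameters(), lr=config.learning_rate)

    def batch_arrays(indices):
        xs = np.stack([dataset[i][0] for i in indices]).astype(np.float32)
        ys = np.stack([dataset[i][1] for i in indices])
        return xs, ys

    def eval_loss(indices) -> float:
        total, nb = 0.0, 0
        for s in range(0, len(indices), config.batch_size):
            xs, ys = batch_arrays(indices[s:s + config.batch_size])
            pred = network(Tensor(xs))
            total += _loss_tensor(loss_kind, ys, pred, int(n_classes)).item()
            nb += 1
        return total / max(nb, 1)

    history = {"train_loss": [], "val_loss": []}
    best_val, best_epoch, best_state = np.inf, -1, network.state_arrays()
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay**epoch
        order = rng.permutation(tr_idx)
        ep_loss, nb = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            xs, ys = batch_arrays(order[s:s + config.batch_size])
            xs, ys = _augment_batch(xs, ys, config.augment_flip_axes,
                                    swap_lr=seg and n_classes == 3, rng=rng)
            pred = network(Tensor(xs))
            loss = _loss_tensor(loss_kind, ys, pred, int(n_classes))
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite {loss_kind} loss at epoch {epoch}, batch {nb} "
                    f"(lr={opt.lr:.2e}); aborting"
                )
            network.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += lval
            nb += 1
        val = eval_loss(va_idx) if va_idx else ep_loss / max(nb, 1)
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(val)
        if verbose:
            print(f"epoch {epoch:3d}  train {ep_loss / max(nb, 1):.4f}  val {val:.4f}")
        if val < best_val:
            best_val, best_epoch, best_state = val, epoch, network.state_arrays()
        elif epoch - best_epoch >= config.early_stopping_patience:
            break

    network.load_state_arrays(best_state)
    return TrainedModel(
        network=network,
        network_config=network_config or NetworkConfig(),
        train_config=config,
        normalization=normalization or NormalizationSpec(),
        history=history,
        best_epoch=best_epoch,
        test_indices=_te_idx,
    )


# -- inference -----------------------------------------------------------------


def predict_mumap(model: TrainedModel, primary_spect: Volume3D,
                  scatter_spect: Volume3D,
                  filter_scatter: bool = True) -> Volume3D:
    """Synthetic attenuation map (cm^-1) from the two SPECT windows."""
    if not primary_spect.same_grid(scatter_spect):
        raise ValueError("primary and scatter windows must share the grid")
    log_max = NormalizationSpec(method="log_maximum")

    def norm_or_zero(vol: Volume3D) -> np.ndarray:
        if vol.data.max() <= 0:
            return np.zeros_like(vol.data, dtype=np.float32)
        return normalize(vol, log_max).data.astype(np.float32)

    scat = scatter_spect
    if filter_scatter:
        scat = butterworth_lowpass(scat)
        scat = scat.with_data(np.clip(scat.data, 0, None))
    x = np.stack([norm_or_zero(primary_spect), norm_or_zero(scat)])[None]
    out = model.network(Tensor(x)).data[0, 0]
    return Volume3D(np.asarray(out, dtype=np.float64), primary_spect.spacing_mm)


def predict_labels(model: TrainedModel, mumap: Volume3D,
                   norm: NormalizationSpec | None = None
                   ) -> tuple[ProbabilityMap, LabelMap]:
    """Kidney probabilities and argmax labels from an attenuation map.

    ``norm`` must match the normalization the model was trained with (it is
    stored on the model; passing None uses the stored spec).
    """
    if norm is None:
        norm = model.normalization
    elif norm != model.normalization:
        raise ValueError(
            f"normalization spec {norm} does not match the model's training-time "
            f"spec {model.normalization}"
        )
    x = normalize(mumap, norm).data.astype(np.float32)[None, None]
    probs = model.network(Tensor(x)).data[0]
    pm = ProbabilityMap(np.asarray(probs, dtype=np.float64), mumap.spacing_mm)
    return pm, pm.argmax_labels()


# -- persistence ---------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Checkpoint: npz weights + embedded JSON metadata block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "network_config": dataclasses.asdict(model.network_config),
        "train_config": dataclasses.asdict(model.train_config),
        "normalization": dataclasses.asdict(model.normalization),
        "best_epoch": model.best_epoch,
        "history": model.history,
        "test_indices": model.test_indices,
        "class_encoding": {"0": "background", "1": "right_kidney", "2": "left_kidney"},
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.network.state_arrays())}
    np.savez(path, metadata=json.dumps(meta), **arrays)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["metadata"]))
        arrays = [z[f"param_{i}"] for i in range(len(z.files) - 1)]
    ncfg_d = meta["network_config"]
    ncfg_d["attention_edge_features"] = ncfg_d.get("attention_edge_features", True)
    ncfg = NetworkConfig(**ncfg_d)
    tcfg_d = meta["train_config"]
    tcfg_d["augment_flip_axes"] = tuple(tcfg_d["augment_flip_axes"])
    tcfg = TrainConfig(**tcfg_d)
    net = build_network(ncfg, seed=0)
    net.load_state_arrays(arrays)
    return TrainedModel(
        network=net,
        network_config=ncfg,
        train_config=tcfg,
        normalization=NormalizationSpec(**meta["normalization"]),
        history=meta["history"],
        best_epoch=meta["best_epoch"],
        test_indices=meta["test_indices"],
    )


# -- ablation harness ----------------------------------------------------------


def ablation_grid(initial_neurons: int = 8, depth: int = 2):
    """The comparison grid: 2 normalizations x 2 losses x 2 class counts x
    3 architectures (conventional, residual, residual+attention)."""
    combos = []
    archs = [("unet", "conventional", False), ("resunet", "residual", False),
             ("resunet_attn", "residual", True)]
    for norm_method in ("windowing_maximum", "maximum"):
        for loss in ("GDSC", "CCE"):
            for n_classes in (3, 2):
                for arch_name, block, attention in archs:
                    name = f"{norm_method}+{loss}+{n_classes}cls+{arch_name}"
                    ncfg = NetworkConfig.for_segmentation(
                        n_classes=n_classes, initial_neurons=initial_neurons,
                        depth=depth, block=block, attention=attention,
                    )
                    norm = NormalizationSpec(method=norm_method)
                    combos.append((name, ncfg, norm, loss))
    return combos


def run_ablation_smoke(cases, steps: int = 1, seed: int = 0,
                       initial_neurons: int = 4, depth: int = 1) -> dict[str, float]:
    """Build every grid combination and run ``steps`` training steps each.

    Returns combo name -> final batch loss; raises if any combination fails to
    build or step.  Meant as a fast structural check of the comparison axes,
    not as a performance measurement.
    """
    results = {}
    for name, ncfg, norm, loss in ablation_grid(initial_neurons, depth):
        data = make_segmentation_dataset(cases, norm, ncfg.n_classes)
        net = build_network(ncfg, seed=seed)
        opt = Adam(net.parameters(), lr=1e-3)
        rng = np.random.default_rng(seed)
        last = np.nan
        for _ in range(steps):
            idx = rng.choice(len(data), size=min(2, len(data)), replace=False)
            xs = np.stack([data[i][0] for i in idx])
            ys = np.stack([data[i][1] for i in idx])
            pred = net(Tensor(xs))
            lt = _loss_tensor(loss, ys, pred, ncfg.n_classes)
            last = lt.item()
            if not np.isfinite(last):
                raise RuntimeError(f"non-finite loss in ablation combo {name}")
            net.zero_grad()
            lt.backward()
            opt.step()
        results[name] = last
    return results
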
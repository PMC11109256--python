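"""Zone classifier: backbone + dual-attention refinement + softmax head.

One independent model is trained per lung zone; each maps a resized zone
crop to a probability vector over the four ILO categories. The architecture
is backbone -> deepest feature map F -> attention refinement -> global
average pooling -> fully connected -> softmax.

Backbones are hand-written CNNs sized for CPU training: ``tiny`` (three
stride-2 blocks, C = 32) is the default for desk-scale experiments;
``deep`` is a larger five-block variant (C = 64). Training follows Adam
with categorical cross-entropy, reduce-on-plateau learning-rate decay
(factor 0.2, patience 10 by default), early stopping on validation loss and
best-weight restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .attention import canonical_variant
from .errors import DataError, DivergenceError, ParameterError, StratificationError
from .preprocess import augment_zone

_BACKBONES: Dict[str, Tuple[Tuple[Tuple[int, int], ...], int]] = {
    # name -> (((out_channels, stride), ...), deepest C)
    "tiny": (((8, 2), (16, 2), (32, 2)), 32),
    "deep": (((16, 2), (32, 2), (32, 1), (64, 2), (64, 1)), 64),
}


@dataclass(frozen=True)
class BackboneSpec:
    """Which convolutional backbone to build.

    ``pretrained`` is accepted for interface compatibility but no pretrained
    weights ship with the package; weights can be loaded from a file after
    construction.
    """

    name: str = "tiny"
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.name not in _BACKBONES:
            raise ParameterError(f"unknown backbone {self.name!r}; expected one of {sorted(_BACKBONES)}")

    @property
    def output_channels(self) -> int:
        return _BACKBONES[self.name][1]


@dataclass
class TrainConfig:
    """Optimisation protocol for one zone model.

    Defaults follow the full-scale protocol: Adam at 1e-4, batch size 4, up
    to 100 epochs, reduce-on-plateau learning-rate decay (factor 0.2,
    patience 10) and early stopping after 10 non-improving epochs. The tiny
    from-scratch backbone in the examples uses a higher rate (1e-3).
    """

    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 100
    lr_reduce_factor: float = 0.2
    lr_patience: int = 10
    early_stop_patience: int = 10
    n_folds: int = 5
    seed: int = 0
    num_classes: int = 4
    augment: bool = False
    augment_params: dict = field(default_factory=dict)
    class_weighted_loss: bool = False

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.lr_patience, self.early_stop_patience, self.n_folds) < 1:
            raise ParameterError("all counts must be positive")
        if not (0 < self.lr_reduce_factor < 1):
            raise ParameterError("lr_reduce_factor must lie in (0, 1)")
        if self.num_classes < 2:
            raise ParameterError("num_classes must be >= 2")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")


@dataclass
class ZonePrediction:
    """Softmax output for one zone crop; argmax ties break to the lower category."""

    image_id: str
    zone_name: str
    probabilities: np.ndarray
    predicted_category: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ParameterError("probabilities must be non-negative and sum to 1")
        self.probabilities = p


@dataclass
class ZoneSamples:
    """All crops of one zone: images (N, H, W), labels (N,), image ids (N,)."""

    zone_name: str
    images: np.ndarray
    labels: np.ndarray
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels) or len(self.labels) != len(self.image_ids):
            raise ParameterError("images, labels and image_ids must have equal length")


def build_model(
    backbone: BackboneSpec = BackboneSpec(),
    variant: str = "sequential",
    ratio: int = 16,
    num_classes: int = 4,
    in_channels: int = 1,
    seed: int = 0,
) -> nn.SequentialModel:
    """Assemble backbone -> attention -> pooled softmax head.

    Two builds with the same arguments and seed have identical initial
    parameters.
    """
    v = canonical_variant(variant)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 797)))
    layers: List[nn.Layer] = []
    ch = in_channels
    blocks, deepest = _BACKBONES[backbone.name]
    for out_ch, stride in blocks:
        layers.append(nn.Conv2D(ch, out_ch, 3, stride, rng))
        layers.append(nn.ReLU())
        ch = out_ch
    assert ch == deepest
    if v == "ca":
        layers.append(nn.ChannelGate(ch, ratio, rng))
    elif v == "sa":
        layers.append(nn.SpatialGate(rng))
    elif v == "sequential":
        layers.append(nn.ChannelGate(ch, ratio, rng))
        layers.append(nn.SpatialGate(rng))
    elif v == "parallel":
        layers.append(nn.ParallelDualGate(ch, ratio, rng))
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(ch, num_classes, rng))
    return nn.SequentialModel(layers)


def stratified_folds(manifest: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Image-level stratified fold assignment (all six zones share a fold).

    Stratifies on ``image_label`` so per-class counts across folds differ by
    at most one. Raises :class:`StratificationError` if any class has fewer
    images than folds.
    """
    labels = manifest["image_label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    too_few = counts[counts < n_folds]
    if not too_few.empty:
        raise StratificationError(
            f"classes with fewer images than folds ({n_folds}): "
            + ", ".join(f"{int(c)}: {int(n)}" for c, n in too_few.items())
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(manifest), dtype=int)
    for k, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[val_idx] = k
    return folds


def _as_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[..., None]
    return x


def train_zone_model(
    samples: ZoneSamples,
    fold_assignment: np.ndarray,
    fold_index: int,
    config: TrainConfig,
    backbone: BackboneSpec = BackboneSpec(),
    variant: str = "sequential",
    ratio: int = 16,
) -> Tuple[nn.SequentialModel, pd.DataFrame]:
    """Train one zone model; ``fold_index`` is the validation fold.

    Returns the model restored to its best-validation-loss weights, plus a
    per-epoch history (epoch, lr, train_loss, val_loss, val_acc).
    """
    folds = np.asarray(fold_assignment)
    val_mask = folds == fold_index
    train_idx = np.where(~val_mask)[0]
    val_idx = np.where(val_mask)[0]
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise DataError(f"empty split for fold {fold_index}: {len(train_idx)} train / {len(val_idx)} val")

    x_train = _as_batch(samples.images[train_idx])
    y_train = np.asarray(samples.labels[train_idx], dtype=int)
    x_val = _as_batch(samples.images[val_idx])
    y_val = np.asarray(samples.labels[val_idx], dtype=int)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, fold_index, 101)))
    model = build_model(backbone, variant, ratio, config.num_classes,
                        in_channels=x_train.shape[3], seed=config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)

    best_val = np.inf
    best_weights = model.get_weights()
    history = []
    lr_wait = stop_wait = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = np.stack(
                    [augment_zone(im[..., 0], rng, **config.augment_params)[..., None] for im in xb]
                )
            model.zero_grad()
            loss, _ = model.loss_and_grad(xb, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            opt.step()
            losses.append(loss)
        val_probs = model.predict_proba(x_val)
        val_loss = nn.cross_entropy(val_probs, y_val)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history.append(
            {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses)),
             "val_loss": val_loss, "val_acc": val_acc}
        )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            lr_wait = stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait >= config.lr_patience:
                opt.lr *= config.lr_reduce_factor
                lr_wait = 0
            if stop_wait >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, pd.DataFrame(history)


def predict_zone(
    model: nn.SequentialModel,
    zone_image: np.ndarray,
    image_id: str = "",
    zone_name: str = "",
) -> ZonePrediction:
    """Classify one resized zone crop."""
    x = _as_batch(np.asarray(zone_image)[None, ...])
    probs = model.predict_proba(x)[0]
    return ZonePrediction(
        image_id=image_id,
        zone_name=zone_name,
        probabilities=probs,
        predicted_category=int(np.argmax(probs)),  # first (lowest) index wins ties
    )


def predict_zone_batch(
    model: nn.SequentialModel,
    samples: ZoneSamples,
    indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Prediction table ``image_id,zone_name,p0..p{K-1},predicted`` for a zone."""
    idx = np.arange(len(samples.images)) if indices is None else np.asarray(indices)
    probs = model.predict_proba(_as_batch(samples.images[idx]))
    k = probs.shape[1]
    frame = pd.DataFrame(
        {"image_id": samples.image_ids[idx], "zone_name": samples.zone_name}
    )
    for c in range(k):
        frame[f"p{c}"] = probs[:, c]
    frame["predicted"] = probs.argmax(axis=1)
    return frame
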
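"""Slice-wise U-Net training: folds, augmentation, transfer learning.

Separate pre- and postoperative models are trained in k-fold
cross-validation (k = 5 by default), with the split made *by patient* so
both of a patient's studies always land in the same fold. The k fold
models are later combined by probability averaging (`ensemble_infer`).

Training minimizes per-slice binary cross-entropy with Adam; the final
activation is a sigmoid, so predictions are probabilities in (0, 1).
Postoperative models can optionally be initialized with the weights of a
fully trained preoperative model (transfer learning), and slices can be
augmented on the fly by random rotation (0-90 deg) and zoom (0-30%),
applied to a configurable fraction of slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .nn import Adam, UNet2D, bce_with_logits

Phase = str


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    The architecture reference gives no depth/width/epoch settings, so all
    are configurable; the defaults are modest CPU-friendly values.
    """

    folds: int = 5
    epochs: int = 4
    batch_size: int = 8
    learning_rate: float = 1e-3
    base_filters: int = 16
    depth: int = 4
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.batch_size < 1 or self.learning_rate <= 0 or self.base_filters < 1:
            raise ValueError("invalid batch size / learning rate / width")


@dataclass(frozen=True)
class AugmentConfig:
    """On-the-fly slice augmentation: rotation and zoom.

    ``sampling_ratio`` is the fraction of training slices that receive an
    augmented transform in each epoch (the remainder pass through
    unchanged); the clinical-scale reference value is 1/255.
    """

    rotation_deg: tuple[float, float] = (0.0, 90.0)
    zoom: tuple[float, float] = (0.0, 0.30)
    sampling_ratio: float = 1.0 / 255.0
    enabled: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.rotation_deg
        if not 0 <= lo <= hi <= 90:
            raise ValueError(f"rotation range must lie in [0, 90], got {self.rotation_deg}")
        zlo, zhi = self.zoom
        if not 0 <= zlo <= zhi <= 0.30:
            raise ValueError(f"zoom range must lie in [0, 0.30], got {self.zoom}")
        if not 0 < self.sampling_ratio <= 1:
            raise ValueError(f"sampling ratio must lie in (0, 1], got {self.sampling_ratio}")


@dataclass(frozen=True)
class FoldSplit:
    """Patient-level partition into k cross-validation folds."""

    assignments: dict[str, int]
    k: int

    def fold_of(self, patient_id: str) -> int:
        return self.assignments[patient_id]

    def val_ids(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f != fold)


def make_folds(patient_ids: Sequence[str], k: int, seed: int) -> FoldSplit:
    """Deterministic patient-level k-fold partition with balanced sizes."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in fold split")
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 555]))
    order = rng.permutation(len(ids))
    assignments = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldSplit(assignments, k)


def augment_slice(
    image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random rotation+zoom to an image/mask pair.

    The identical spatial transform hits both arrays; the image is
    interpolated linearly and the mask nearest-neighbor, so labels stay
    binary. Zoom factor z in [1, 1.3] magnifies about the slice center.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {image.shape} vs {mask.shape}")
    angle = float(rng.uniform(*cfg.rotation_deg))
    zoom = 1.0 + float(rng.uniform(*cfg.zoom))
    theta = np.deg2rad(angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    # affine_transform maps output coords to input: inverse transform.
    matrix = rot.T / zoom
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - matrix @ center
    img_out = ndimage.affine_transform(
        image.astype(float), matrix, offset=offset, order=1, mode="constant",
        cval=float(image.min()),
    )
    mask_out = ndimage.affine_transform(
        mask.astype(float), matrix, offset=offset, order=0, mode="constant", cval=0.0
    )
    return img_out, (mask_out > 0.5).astype(mask.dtype)


@dataclass
class TrainedModel:
    """A trained fold model: network weights plus training provenance."""

    net: UNet2D
    phase: Phase
    fold: int
    history: list[float] = field(default_factory=list)

    def predict(self, slices: np.ndarray) -> np.ndarray:
        """Per-slice foreground probability for a (N, H, W) stack."""
        x = np.asarray(slices)
        if x.ndim == 2:
            x = x[None]
        return self.net.predict_proba(x[:, None])[:, 0]

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (+ a JSON sidecar with meta) to ``path``.npz."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        meta = {
            "phase": self.phase,
            "fold": self.fold,
            "depth": self.net.depth,
            "base_filters": self.net.base_filters,
            "in_channels": self.net.in_channels,
            "dtype": str(self.net.dtype),
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = UNet2D(
            depth=meta["depth"], base_filters=meta["base_filters"],
            in_channels=meta["in_channels"], dtype=np.dtype(meta["dtype"]),
        )
        with np.load(path.with_suffix(".npz")) as z:
            net.load_state_dict({k: z[k] for k in z.files})
        return cls(net, meta["phase"], meta["fold"], list(meta["history"]))


def train_fold(
    train_images: np.ndarray,
    train_masks: np.ndarray,
    cfg: TrainConfig,
    *,
    phase: Phase = "preop",
    fold: int = 0,
    augment: AugmentConfig | None = None,
    init_model: TrainedModel | None = None,
) -> TrainedModel:
    """Train one fold model on (N, H, W) slice stacks.

    `init_model` seeds the weights (transfer learning); otherwise they are
    He-initialized from the config seed. The loop is fully seeded: shuffle
    order and augmentation draws derive from ``cfg.seed`` and ``fold``.

    Raises on empty input, shape mismatch, or NaN loss.
    """
    x = np.asarray(train_images, dtype=float)
    y = np.asarray(train_masks, dtype=float)
    if x.ndim != 3 or x.shape != y.shape or x.shape[0] == 0:
        raise ValueError(f"expected matching nonempty (N,H,W) stacks, got {x.shape} / {y.shape}")

    dtype = np.dtype(cfg.dtype)
    if init_model is not None:
        net = UNet2D(init_model.net.depth, init_model.net.base_filters,
                     init_model.net.in_channels, dtype=init_model.net.dtype)
        net.load_state_dict(init_model.net.state_dict())
    else:
        net = UNet2D(cfg.depth, cfg.base_filters,
                     seed=np.random.SeedSequence([cfg.seed, 31, fold]).generate_state(1)[0] % (2**31),
                     dtype=dtype)
    opt = Adam(net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77, fold]))

    n = x.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb = x[sel].copy()
            yb = y[sel].copy()
            if augment is not None and augment.enabled:
                hit = rng.uniform(size=len(sel)) < augment.sampling_ratio
                for i in np.flatnonzero(hit):
                    xb[i], yb[i] = augment_slice(xb[i], yb[i], augment, rng)
            logits = net.forward(xb[:, None].astype(dtype), train=True)
            loss, dlogits = bce_with_logits(logits, yb[:, None].astype(dtype))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(net, phase, fold, history)


def transfer_init(preop_model: TrainedModel, cfg: TrainConfig | None = None) -> TrainedModel:
    """Clone a trained preoperative model as the postoperative starting point.

    Before any training step the clone's predictions are bit-identical to
    the donor's; subsequent training of the clone never touches the donor.
    A config requesting a different architecture is rejected.
    """
    if cfg is not None and (cfg.depth != preop_model.net.depth
                            or cfg.base_filters != preop_model.net.base_filters):
        raise ValueError(
            f"architecture mismatch: donor depth/filters "
            f"{preop_model.net.depth}/{preop_model.net.base_filters}, "
            f"config requests {cfg.depth}/{cfg.base_filters}"
        )
    net = UNet2D(preop_model.net.depth, preop_model.net.base_filters,
                 preop_model.net.in_channels, dtype=preop_model.net.dtype)
    net.load_state_dict(preop_model.net.state_dict())
    return TrainedModel(net, "postop", preop_model.fold, [])
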
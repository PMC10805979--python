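"""Slice-wise inference, fold-ensemble averaging, and threshold binarization.

A conformed volume is cut into coronal slices, each slice goes through a
fold model, and the per-slice probability maps are restacked into a
`ProbabilityGrid`. The k fold grids are combined by a plain voxel-wise
mean, then binarized at a phase-specific cutoff: 0.6 preoperatively,
0.44 postoperatively. Ties at exactly the threshold count as foreground.
Postoperative masks additionally pass through the morphological cleanup in
`postproc`; preoperative masks do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import CORONAL_AXIS, MaskGrid, VolumeGrid, is_ras
from .postproc import PostprocConfig, postprocess_postop
from .unet import TrainedModel

#: Probability cutoffs used to binarize ensemble predictions.
THRESHOLD_PREOP = 0.6
THRESHOLD_POSTOP = 0.44


@dataclass(frozen=True)
class EnsembleConfig:
    threshold_preop: float = THRESHOLD_PREOP
    threshold_postop: float = THRESHOLD_POSTOP

    def __post_init__(self) -> None:
        for t in (self.threshold_preop, self.threshold_postop):
            if not 0 < t < 1:
                raise ValueError(f"threshold must lie in (0,1), got {t}")

    def threshold_for(self, phase: str) -> float:
        return self.threshold_preop if phase == "preop" else self.threshold_postop


@dataclass
class ProbabilityGrid:
    """Per-voxel foreground probability on the same lattice as its source."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"probability grid must be rank 3, got {self.data.ndim}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def predict_volume(
    model: TrainedModel, vol: VolumeGrid, batch_size: int = 16
) -> ProbabilityGrid:
    """Run one fold model over every coronal slice and restack."""
    if not is_ras(vol):
        raise ValueError("predict_volume expects a RAS-conformed volume")
    slices = np.moveaxis(vol.data, CORONAL_AXIS, 0)  # (A, R, S)
    probs = np.empty_like(slices, dtype=float)
    for start in range(0, slices.shape[0], batch_size):
        batch = slices[start : start + batch_size]
        probs[start : start + batch.shape[0]] = model.predict(batch)
    return ProbabilityGrid(np.moveaxis(probs, 0, CORONAL_AXIS), vol.affine.copy())


def ensemble_average(probs: Sequence[ProbabilityGrid]) -> ProbabilityGrid:
    """Voxel-wise mean of fold predictions (equal weights)."""
    probs = list(probs)
    if not probs:
        raise ValueError("ensemble_average needs at least one grid")
    shape = probs[0].data.shape
    for p in probs[1:]:
        if p.data.shape != shape:
            raise ValueError(f"shape mismatch in ensemble: {p.data.shape} vs {shape}")
    mean = np.mean([p.data for p in probs], axis=0)
    return ProbabilityGrid(mean, probs[0].affine.copy())


def binarize(prob: ProbabilityGrid, threshold: float) -> MaskGrid:
    """Threshold probabilities; a voxel at exactly the cutoff is foreground."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return MaskGrid((prob.data >= threshold).astype(np.uint8), prob.affine.copy())


def segment_study(
    models: Sequence[TrainedModel],
    vol: VolumeGrid,
    *,
    ensemble_cfg: EnsembleConfig | None = None,
    postproc_cfg: PostprocConfig | None = None,
) -> MaskGrid:
    """Full inference for one study: predict, average, binarize, clean up.

    The binarization threshold follows ``vol.phase``; morphological
    postprocessing is applied to postoperative studies only.
    """
    ensemble_cfg = ensemble_cfg or EnsembleConfig()
    grids = [predict_volume(m, vol) for m in models]
    mean = ensemble_average(grids)
    mask = binarize(mean, ensemble_cfg.threshold_for(vol.phase))
    if vol.phase == "postop":
        mask = postprocess_postop(mask, postproc_cfg or PostprocConfig())
    return mask
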
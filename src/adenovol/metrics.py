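"""Segmentation similarity metrics: Dice, Jaccard, 95th-percentile Hausdorff.

Empty masks need explicit conventions, because postoperative cohorts are
full of them (a gross-total resection has an empty truth mask, and a model
may rightly predict nothing):

* both masks empty — perfect agreement by default: Dice = Jaccard = 1,
  HD95 = 0 mm. A compatibility switch (``both_empty_score``) scores the
  overlap metrics 0 instead, for comparison with conventions that treat
  empties as failures.
* exactly one mask empty — Dice = Jaccard = 0 and HD95 = NaN (the distance
  to an empty surface is undefined).

HD95 is computed on boundary voxels — foreground voxels with at least one
background 6-neighbor, the lattice border counting as background — as the
maximum of the two directed 95th-percentile Euclidean surface distances,
in mm. Percentiles use the linear-interpolation quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def _as_bool(mask) -> np.ndarray:
    if not isinstance(mask, np.ndarray) and hasattr(mask, "data"):
        mask = mask.data
    return np.asarray(mask).astype(bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def dice(a, b, *, both_empty_score: float = 1.0) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) in [0, 1]."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return float(both_empty_score)
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard(a, b, *, both_empty_score: float = 1.0) -> float:
    """Jaccard overlap |A∩B| / |A∪B| in [0, 1]."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    union = int((a | b).sum())
    if union == 0:
        return float(both_empty_score)
    return int((a & b).sum()) / union


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background 6-neighbor (border = background)."""
    mask = _as_bool(mask)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def hd95(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask surfaces, mm.

    Identical masks give 0; both empty gives 0; exactly one empty gives NaN.
    """
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    spacing = np.asarray(spacing, dtype=float)
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return float("nan")
    ba, bb = boundary_voxels(a), boundary_voxels(b)
    # EDT of the complement of a surface = distance to that surface.
    dist_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    d_ab = np.percentile(dist_to_b[ba], 95)
    d_ba = np.percentile(dist_to_a[bb], 95)
    return float(max(d_ab, d_ba))


@dataclass(frozen=True)
class MetricReport:
    """Per-case similarity metrics plus the empty-mask policy applied."""

    dice: float
    jaccard: float
    hd95_mm: float
    both_empty_score: float = 1.0


def evaluate_masks(pred, truth, spacing=(1.0, 1.0, 1.0), *,
                   both_empty_score: float = 1.0) -> MetricReport:
    return MetricReport(
        dice=dice(pred, truth, both_empty_score=both_empty_score),
        jaccard=jaccard(pred, truth, both_empty_score=both_empty_score),
        hd95_mm=hd95(pred, truth, spacing),
        both_empty_score=both_empty_score,
    )


def summarize(values, nan_policy: str = "propagate") -> dict[str, float]:
    """Mean ± SD and median (IQR) of a metric column.

    ``nan_policy='propagate'`` keeps NaNs (a single undefined case makes
    the aggregate NaN, as happens when a model predicts nothing on every
    case); ``'omit'`` drops them first.
    """
    v = np.asarray(values, dtype=float)
    if nan_policy == "omit":
        v = v[~np.isnan(v)]
    elif nan_policy != "propagate":
        raise ValueError(f"unknown nan_policy {nan_policy!r}")
    if v.size == 0:
        return {"mean": float("nan"), "sd": float("nan"),
                "median": float("nan"), "iqr": float("nan"), "n": 0}
    q75, q25 = np.percentile(v, [75, 25]) if not np.isnan(v).any() else (float("nan"),) * 2
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
        "iqr": float(q75 - q25),
        "n": int(v.size),
    }
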
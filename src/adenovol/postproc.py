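"""Postoperative mask cleanup: drop specks, fill holes, dilate.

Postoperative predictions are noisy — scattered false-positive specks and
pinholes inside true residual. The cleanup applies, in order:

1. remove connected components smaller than a size floor (default 50
   voxels; at the canonical 1 mm grid, 50 mm^3) using 26-connectivity;
2. fill enclosed cavities (background regions with no 6-connected path to
   the lattice boundary);
3. one binary dilation with a 3x3x3 cube, rounding corners toward more
   tumor-like shapes.

Dilation can merge or regrow regions, so the size floor is guaranteed only
before step 3 — any sub-floor component in the output stems from
dilation-induced growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 26- and 6-neighborhood structuring elements.
CONN26 = np.ones((3, 3, 3), dtype=bool)
CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PostprocConfig:
    min_component_voxels: int = 50
    dilation_iterations: int = 1

    def __post_init__(self) -> None:
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")

    @property
    def structuring_element(self) -> np.ndarray:
        return CONN26


def _as_bool(mask) -> np.ndarray:
    if not isinstance(mask, np.ndarray) and hasattr(mask, "data"):
        mask = mask.data
    return np.asarray(mask).astype(bool)


def _like(mask, data: np.ndarray):
    from .grids import MaskGrid  # local import to avoid a cycle

    if not isinstance(mask, np.ndarray) and hasattr(mask, "affine"):
        return MaskGrid(data.astype(np.uint8), mask.affine.copy())
    return data.astype(np.uint8)


def remove_small_components(mask, min_size: int):
    """Delete every 26-connected component with fewer than `min_size` voxels."""
    data = _as_bool(mask)
    labels, n = ndimage.label(data, structure=CONN26)
    if n == 0:
        return _like(mask, data)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return _like(mask, keep[labels])


def fill_holes(mask):
    """Fill background cavities with no 6-connected path to the boundary."""
    data = _as_bool(mask)
    return _like(mask, ndimage.binary_fill_holes(data, structure=CONN6))


def dilate(mask, cfg: PostprocConfig | None = None):
    """Binary dilation by the configured structuring element."""
    cfg = cfg or PostprocConfig()
    data = _as_bool(mask)
    if cfg.dilation_iterations == 0:
        return _like(mask, data)
    out = ndimage.binary_dilation(
        data, structure=cfg.structuring_element, iterations=cfg.dilation_iterations
    )
    return _like(mask, out)


def postprocess_postop(mask, cfg: PostprocConfig | None = None):
    """The full cleanup: remove small components, fill holes, dilate."""
    cfg = cfg or PostprocConfig()
    out = remove_small_components(mask, cfg.min_component_voxels)
    out = fill_holes(out)
    return dilate(out, cfg)
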
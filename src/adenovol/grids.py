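"""Volume containers and canonical-grid conformation.

Every stage of the volumetry pipeline operates on a volume that has been
conformed to a canonical lattice: RAS orientation (first/second/third voxel
axes increasing toward the patient's Right/Anterior/Superior), isotropic
voxel spacing, a fixed cubic shape, and per-study z-scored intensities.
The clinical-scale canonical grid is 256^3 voxels at 1.0 mm; the grid is a
parameter (`GridSpec`) so that desk-scale work can run the identical code
paths at e.g. 64^3.

Coronal slices -- the 2D network's input -- are planes of constant
anterior-posterior coordinate, i.e. slices along axis 1 of a RAS volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

Phase = Literal["preop", "postop"]

#: Clinical-scale canonical lattice constants.
CANONICAL_SHAPE = (256, 256, 256)
CANONICAL_SPACING_MM = 1.0

#: Index of the anterior-posterior axis in a RAS voxel lattice.
CORONAL_AXIS = 1


@dataclass(frozen=True)
class GridSpec:
    """Target lattice for conformation.

    Parameters
    ----------
    shape:
        Target grid shape in voxels. The clinical default is 256^3; tests
        and phantoms typically use 64^3.
    spacing:
        Target isotropic voxel edge length in mm.
    orientation_code:
        Axis convention of the conformed volume. Only "RAS" is supported.
    """

    shape: tuple[int, int, int] = CANONICAL_SHAPE
    spacing: float = CANONICAL_SPACING_MM
    orientation_code: str = "RAS"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"grid shape must be 3 entries >= 8, got {self.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.orientation_code != "RAS":
            raise ValueError("only RAS orientation is supported")

    @property
    def affine(self) -> np.ndarray:
        """Diagonal RAS affine centering the grid on the world origin."""
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = -self.spacing * (np.asarray(self.shape) - 1) / 2.0
        return aff


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("orientation matrix is singular")
    return affine


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel-to-world affine and surgical phase.

    ``data[i, j, k]`` sits at world coordinate ``affine @ (i, j, k, 1)``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    phase: Phase = "preop"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be rank 3, got rank {self.data.ndim}")
        self.affine = _check_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, idx: Sequence[float]) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        v = np.ones(4)
        v[:3] = idx
        return (self.affine @ v)[:3]


@dataclass
class MaskGrid:
    """A binary segmentation on the same lattice family as `VolumeGrid`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be rank 3, got rank {arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:8]}")
        self.data = arr.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class Slice2D:
    """One coronal plane extracted from a RAS volume."""

    data: np.ndarray
    index: int
    parent_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not 0 <= self.index < self.parent_shape[CORONAL_AXIS]:
            raise ValueError(
                f"slice index {self.index} outside coronal extent "
                f"{self.parent_shape[CORONAL_AXIS]}"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | Path, phase: Phase = "preop") -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj, dtype=np.float64), img.affine, phase)


def load_mask(path: str | Path) -> MaskGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return MaskGrid((data > 0.5).astype(np.uint8), img.affine)


def save_volume(vol: VolumeGrid | MaskGrid, path: str | Path) -> None:
    data = vol.data
    if isinstance(vol, MaskGrid):
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Reorientation
# ---------------------------------------------------------------------------

def _axis_dominance(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosines between voxel axes and their dominant world axes."""
    rot = affine[:3, :3]
    norms = np.linalg.norm(rot, axis=0)
    cosines = np.abs(rot) / norms
    dominant = np.argmax(cosines, axis=0)
    return dominant, cosines.max(axis=0)


def reorient_ras(
    vol: VolumeGrid, *, max_obliquity_deg: float = 10.0
) -> VolumeGrid:
    """Permute/flip voxel axes so they increase toward Right/Anterior/Superior.

    Voxel data are only permuted and flipped, and the affine is updated
    accordingly, so the world coordinate of every voxel is unchanged.
    A residual in-plane obliquity (below `max_obliquity_deg`) is preserved
    in the affine, as is standard for closest-canonical reorientation.

    Raises
    ------
    ValueError
        If the affine is singular, if the voxel axes do not map one-to-one
        onto world axes, or if any axis is oblique beyond the tolerance.
    """
    dominant, cosines = _axis_dominance(vol.affine)
    if set(dominant.tolist()) != {0, 1, 2}:
        raise ValueError(
            "cannot reorient: voxel axes do not map one-to-one onto world axes "
            f"(dominant axes {dominant.tolist()})"
        )
    min_cos = float(np.cos(np.deg2rad(max_obliquity_deg)))
    if np.any(cosines < min_cos):
        angles = np.rad2deg(np.arccos(np.clip(cosines, -1, 1)))
        raise ValueError(
            f"cannot reorient: obliquity {angles.round(2).tolist()} deg exceeds "
            f"tolerance {max_obliquity_deg} deg"
        )
    ornt = nib.orientations.io_orientation(vol.affine)
    data = nib.orientations.apply_orientation(vol.data, ornt)
    affine = vol.affine @ nib.orientations.inv_ornt_aff(ornt, vol.shape)
    return VolumeGrid(data, affine, vol.phase)


def is_ras(vol: VolumeGrid) -> bool:
    return nib.orientations.aff2axcodes(vol.affine) == ("R", "A", "S")


# ---------------------------------------------------------------------------
# Resampling / conformation / normalization
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: VolumeGrid, target_spacing: float, *, is_mask: bool = False
) -> VolumeGrid:
    """Resample to isotropic `target_spacing` mm preserving the field of view.

    Images are interpolated linearly; masks nearest-neighbor so labels stay
    binary. The output shape is round(shape * spacing / target) per axis.
    """
    if not target_spacing > 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if any(s < 2 for s in vol.shape):
        raise ValueError(f"degenerate input shape {vol.shape}: every axis needs >= 2 voxels")
    factors = vol.spacing / target_spacing
    if np.allclose(factors, 1.0, atol=1e-9):
        return VolumeGrid(vol.data.copy(), vol.affine.copy(), vol.phase)
    new_shape = np.maximum(np.round(np.asarray(vol.shape) * factors), 1).astype(int)
    # ndimage.zoom maps output index i to input index i / zoom with
    # zoom = (out - 1)/(in - 1) under grid_mode=False; use grid extent scaling.
    order = 0 if is_mask else 1
    data = ndimage.zoom(
        vol.data.astype(float),
        zoom=new_shape / np.asarray(vol.shape),
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    if is_mask:
        data = (data > 0.5).astype(np.uint8)
    # Scale affine columns to the new spacing. grid_mode=True preserves the
    # array *extent*, so the first voxel center shifts by half the spacing
    # difference; absorb that into the translation.
    affine = vol.affine.copy()
    dirs = affine[:3, :3] / vol.spacing
    affine[:3, :3] = dirs * target_spacing
    affine[:3, 3] = vol.affine[:3, 3] + dirs @ ((target_spacing - vol.spacing) / 2.0)
    return VolumeGrid(data, affine, vol.phase)


def conform_grid(
    vol: VolumeGrid, spec: GridSpec, *, is_mask: bool = False
) -> VolumeGrid:
    """Center-crop and/or symmetrically pad to `spec.shape`.

    Pad value is the image minimum (background intensity) for images and 0
    for masks. For an odd crop/pad remainder the extra voxel goes to the
    high-index side, so pad-then-crop round trips exactly.
    """
    if not np.allclose(vol.spacing, spec.spacing, atol=1e-6):
        raise ValueError(
            f"conform_grid expects isotropic spacing {spec.spacing}, got {vol.spacing}"
        )
    data = vol.data
    pad_value = 0 if is_mask else float(data.min()) if data.size else 0.0
    affine = vol.affine.copy()
    dirs = affine[:3, :3]
    for ax, target in enumerate(spec.shape):
        cur = data.shape[ax]
        if cur == target:
            continue
        if cur > target:
            excess = cur - target
            lo = excess // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(lo, lo + target)
            data = data[tuple(sl)]
            affine[:3, 3] = affine[:3, 3] + dirs[:, ax] * lo
        else:
            deficit = target - cur
            lo = deficit // 2
            hi = deficit - lo
            pad = [(0, 0)] * 3
            pad[ax] = (lo, hi)
            data = np.pad(data, pad, mode="constant", constant_values=pad_value)
            affine[:3, 3] = affine[:3, 3] - dirs[:, ax] * lo
    if is_mask:
        data = data.astype(np.uint8)
    return VolumeGrid(data, affine, vol.phase)


def normalize_intensity(vol: VolumeGrid) -> VolumeGrid:
    """Per-study z-score: zero mean, unit standard deviation.

    A constant volume (zero variance) maps to all zeros rather than NaN.
    The transform is invariant to positive affine intensity rescaling, so
    scanner-dependent intensity scales drop out.
    """
    data = vol.data.astype(float)
    sd = float(data.std())
    if sd < 1e-12:
        out = np.zeros_like(data)
    else:
        out = (data - data.mean()) / sd
    return VolumeGrid(out, vol.affine.copy(), vol.phase)


# ---------------------------------------------------------------------------
# Coronal slicing
# ---------------------------------------------------------------------------

def slice_coronal(vol: VolumeGrid) -> list[Slice2D]:
    """Split a RAS volume into coronal planes, anterior coordinate ascending."""
    if not is_ras(vol):
        raise ValueError(
            f"slice_coronal requires a RAS volume, got axes "
            f"{nib.orientations.aff2axcodes(vol.affine)}"
        )
    return [
        Slice2D(vol.data[:, k, :], k, vol.shape)
        for k in range(vol.shape[CORONAL_AXIS])
    ]


def stack_coronal(
    slices: Iterable[Slice2D], affine: np.ndarray | None = None,
    phase: Phase = "preop",
) -> VolumeGrid:
    """Reassemble coronal slices into a volume; inverse of `slice_coronal`."""
    slices = sorted(slices, key=lambda s: s.index)
    if not slices:
        raise ValueError("cannot stack an empty slice sequence")
    shape = slices[0].parent_shape
    expect = list(range(shape[CORONAL_AXIS]))
    if [s.index for s in slices] != expect:
        raise ValueError("slice indices do not cover the coronal extent exactly once")
    data = np.stack([s.data for s in slices], axis=CORONAL_AXIS)
    if affine is None:
        affine = np.eye(4)
    return VolumeGrid(data, affine, phase)


# ---------------------------------------------------------------------------
# Full preprocessing chain
# ---------------------------------------------------------------------------

def preprocess_image(vol: VolumeGrid, spec: GridSpec | None = None) -> VolumeGrid:
    """Conform an image: reorient -> resample -> crop/pad -> z-score."""
    spec = spec or GridSpec()
    v = reorient_ras(vol)
    v = resample_isotropic(v, spec.spacing)
    v = conform_grid(v, spec)
    return normalize_intensity(v)


def preprocess_mask(mask: MaskGrid, spec: GridSpec | None = None) -> MaskGrid:
    """Conform a mask with nearest-neighbor interpolation and zero padding."""
    spec = spec or GridSpec()
    as_vol = VolumeGrid(mask.data.astype(float), mask.affine)
    v = reorient_ras(as_vol)
    v = resample_isotropic(v, spec.spacing, is_mask=True)
    v = conform_grid(v, spec, is_mask=True)
    return MaskGrid((v.data > 0.5).astype(np.uint8), v.affine)
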
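"""Synthetic sellar phantoms: seeded pre/postoperative study pairs.

No public imaging cohort exists for this task, so the test bed is a phantom
generator that emulates the *structure* of a transsphenoidal-surgery cohort:
a contrast-enhancing, possibly lobulated tumor (union of 1-3 overlapping
ellipsoids) sitting on a smooth noisy background, and a postoperative study
in which a known fraction of the tumor volume remains. Ground-truth masks
and reference volumes come with every study, and a configurable fraction of
the cohort has zero residual (gross total resection) so the GTR confusion
machinery can be exercised end to end.

All randomness flows from a single seed: patient ``P007`` of cohort seed 42
is bit-identical across runs and machines.

The generator makes no attempt at anatomical or MR-physics realism (no bias
fields, no Rician noise, no cavernous-sinus geometry); it provides bright
compact lesions that a small network can learn quickly, plus exact truth.
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, MaskGrid, VolumeGrid


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom cohort.

    Attributes
    ----------
    grid:
        Canonical lattice of the generated studies (desk scale 64^3, 1 mm).
    tumor_radii_range:
        Min/max semi-axis of the primary ellipsoid, mm.
    n_lobes_range:
        Number of overlapping ellipsoids forming the tumor (1 = pure
        ellipsoid with an analytic volume).
    center_jitter:
        Max displacement of the tumor center from the grid center, mm.
    tumor_contrast:
        Mean intensity added inside the tumor, in units of the background
        noise scale (contrast-enhancement analogue).
    noise_sd:
        Standard deviation of the additive voxel noise.
    residual_fraction_range:
        Uniform range of the postoperative residual fraction for non-GTR
        cases (the lower bound stays above 0 so "residual present" is
        unambiguous).
    gtr_fraction:
        Fraction of cohort patients with residual fraction exactly 0.
    seed:
        Master seed; every per-patient stream derives from it.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(shape=(64, 64, 64), spacing=1.0))
    tumor_radii_range: tuple[float, float] = (6.0, 12.0)
    n_lobes_range: tuple[int, int] = (1, 3)
    center_jitter: float = 4.0
    tumor_contrast: float = 3.0
    noise_sd: float = 0.5
    residual_fraction_range: tuple[float, float] = (0.05, 0.5)
    gtr_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tumor_radii_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid radii range {self.tumor_radii_range}")
        extent = min(self.grid.shape) * self.grid.spacing
        if 2 * hi + 2 * self.center_jitter >= extent:
            raise ValueError(
                f"tumor (radius {hi} mm + jitter {self.center_jitter} mm) does not "
                f"fit in a {extent} mm grid"
            )
        rlo, rhi = self.residual_fraction_range
        if not (0 <= rlo <= rhi <= 1):
            raise ValueError(f"residual fractions must lie in [0,1], got {self.residual_fraction_range}")
        if not 0 <= self.gtr_fraction <= 1:
            raise ValueError(f"gtr_fraction must lie in [0,1], got {self.gtr_fraction}")


@dataclass
class Study:
    """One acquisition: image plus ground-truth mask."""

    image: VolumeGrid
    mask: MaskGrid


@dataclass
class StudyPair:
    """A patient's linked pre- and postoperative studies with ground truth."""

    patient_id: str
    preop: Study
    postop: Study
    true_preop_volume_mm3: float
    residual_fraction: float

    def __post_init__(self) -> None:
        if self.preop.mask.voxel_count() == 0:
            raise ValueError(f"{self.patient_id}: preoperative mask is empty")
        extra = self.postop.mask.data & ~self.preop.mask.data
        if extra.any():
            raise ValueError(
                f"{self.patient_id}: postoperative mask leaves the preoperative tumor region"
            )


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Deterministic per-patient stream: master seed x stable id hash."""
    tag = zlib.crc32(str(patient_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def _ellipsoid_inside(coords_mm: list[np.ndarray], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords_mm, center, radii))
    return q <= 1.0


def _voxelize_lobes(
    grid: GridSpec, lobes: list[tuple[np.ndarray, np.ndarray]], supersample: int = 1
) -> np.ndarray:
    """Boolean union of ellipsoids on the lattice (voxel-center test)."""
    s = grid.spacing / supersample
    shape = tuple(n * supersample for n in grid.shape)
    axes = [
        (np.arange(n) + 0.5) * s
        for n in shape
    ]
    coords = list(np.meshgrid(*axes, indexing="ij", sparse=True))
    inside = np.zeros(shape, dtype=bool)
    for center, radii in lobes:
        inside |= _ellipsoid_inside(coords, center, radii)
    return inside


def _draw_lobes(cfg: PhantomConfig, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    extent = np.asarray(cfg.grid.shape) * cfg.grid.spacing
    center = extent / 2 + rng.uniform(-cfg.center_jitter, cfg.center_jitter, size=3)
    lo, hi = cfg.tumor_radii_range
    radii = rng.uniform(lo, hi, size=3)
    lobes = [(center, radii)]
    n_lobes = int(rng.integers(cfg.n_lobes_range[0], cfg.n_lobes_range[1] + 1))
    for _ in range(n_lobes - 1):
        # Satellite lobe centered inside the primary ellipsoid: union stays
        # connected and within the primary's bounding box + its own radius.
        u = rng.uniform(-0.6, 0.6, size=3)
        sat_center = center + u * radii
        sat_radii = radii * rng.uniform(0.4, 0.7, size=3)
        lobes.append((sat_center, sat_radii))
    for c, r in lobes:
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise ValueError("tumor lobe does not fit inside the grid")
    return lobes


def _background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field standing in for brain parenchyma."""
    field_ = rng.normal(0.0, 1.0, size=cfg.grid.shape)
    field_ = ndimage.gaussian_filter(field_, sigma=8.0)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd * 0.5
    return field_


def make_phantom(
    cfg: PhantomConfig,
    patient_id: str,
    residual_fraction: float | None = None,
) -> StudyPair:
    """Generate one seeded pre/postoperative study pair.

    Deterministic given ``(cfg.seed, patient_id)``. If `residual_fraction`
    is None it is drawn: 0 with probability ``cfg.gtr_fraction``, else
    uniform over ``cfg.residual_fraction_range``.
    """
    rng = _patient_rng(cfg.seed, patient_id)
    lobes = _draw_lobes(cfg, rng)

    pre_mask = _voxelize_lobes(cfg.grid, lobes).astype(np.uint8)
    # Reference volume by 2x-supersampled voxelization: exact enough
    # (<~1% for mm-scale radii) to serve as ground truth for volumetry.
    fine = _voxelize_lobes(cfg.grid, lobes, supersample=2)
    true_volume = float(fine.sum()) * (cfg.grid.spacing / 2) ** 3

    background = _background(cfg, rng)
    noise_pre = rng.normal(0.0, cfg.noise_sd, size=cfg.grid.shape)
    affine = cfg.grid.affine
    pre_image = VolumeGrid(
        background + cfg.tumor_contrast * pre_mask + noise_pre, affine, "preop"
    )

    if residual_fraction is None:
        if rng.uniform() < cfg.gtr_fraction:
            residual_fraction = 0.0
        else:
            residual_fraction = float(rng.uniform(*cfg.residual_fraction_range))
    if not 0 <= residual_fraction <= 1:
        raise ValueError(f"residual fraction must lie in [0,1], got {residual_fraction}")

    post_mask_arr = _carve_residual(pre_mask.astype(bool), residual_fraction, rng)
    noise_post = rng.normal(0.0, cfg.noise_sd, size=cfg.grid.shape)
    post_image = VolumeGrid(
        background + cfg.tumor_contrast * post_mask_arr + noise_post, affine, "postop"
    )

    return StudyPair(
        patient_id=str(patient_id),
        preop=Study(pre_image, MaskGrid(pre_mask, affine)),
        postop=Study(post_image, MaskGrid(post_mask_arr.astype(np.uint8), affine)),
        true_preop_volume_mm3=true_volume,
        residual_fraction=float(residual_fraction),
    )


def _carve_residual(
    pre_mask: np.ndarray, residual_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Grow a connected residual of exactly the target size from one side.

    A random direction picks the "far wall" of the resection cavity; the
    residual is grown voxel by voxel from the most distal tumor voxel,
    always extending along the 6-neighborhood, preferring distal voxels.
    This mimics a residual rim left at the margin of the cavity and
    guarantees a connected region of exactly ``round(f * N)`` voxels.
    """
    total = int(pre_mask.sum())
    target = int(round(residual_fraction * total))
    if target == 0:
        return np.zeros_like(pre_mask, dtype=bool)
    if target >= total:
        return pre_mask.copy()

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    idx = np.argwhere(pre_mask)
    proj = idx @ direction
    # Highest-projection voxel seeds the residual.
    seed = tuple(idx[np.argmax(proj)])

    proj_map = np.zeros(pre_mask.shape)
    proj_map[tuple(idx.T)] = proj
    residual = np.zeros_like(pre_mask, dtype=bool)
    # Max-heap on projection (python heapq is a min-heap -> negate).
    heap: list[tuple[float, tuple[int, int, int]]] = [(-proj_map[seed], seed)]
    queued = {seed}
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    count = 0
    shape = pre_mask.shape
    while heap and count < target:
        _, vox = heapq.heappop(heap)
        residual[vox] = True
        count += 1
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and pre_mask[nb]
                and nb not in queued
            ):
                queued.add(nb)
                heapq.heappush(heap, (-proj_map[nb], nb))
    return residual


def simulate_resection(
    pair: StudyPair, residual_fraction: float, seed: int
) -> StudyPair:
    """Re-derive the postoperative study of `pair` at a new residual fraction.

    The preoperative study is untouched; the resected signal is replaced by
    background-level intensity (background field + noise, no contrast).
    """
    if not 0 <= residual_fraction <= 1:
        raise ValueError(f"residual fraction must lie in [0,1], got {residual_fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 919]))
    pre_mask = pair.preop.mask.data.astype(bool)
    residual = _carve_residual(pre_mask, residual_fraction, rng)
    affine = pair.preop.image.affine
    # Background estimate: preop image with tumor signal stripped.
    contrast = _estimate_contrast(pair.preop.image.data, pre_mask)
    post_image = pair.preop.image.data - contrast * pre_mask + contrast * residual
    post_image = post_image + rng.normal(0.0, 1e-3, size=post_image.shape)
    return StudyPair(
        patient_id=pair.patient_id,
        preop=pair.preop,
        postop=Study(
            VolumeGrid(post_image, affine, "postop"),
            MaskGrid(residual.astype(np.uint8), affine),
        ),
        true_preop_volume_mm3=pair.true_preop_volume_mm3,
        residual_fraction=float(residual_fraction),
    )


def _estimate_contrast(image: np.ndarray, mask: np.ndarray) -> float:
    inside = float(image[mask].mean())
    outside = float(image[~mask].mean())
    return inside - outside


def make_cohort(
    n: int, cfg: PhantomConfig, seed: int | None = None
) -> tuple[list[StudyPair], pd.DataFrame]:
    """Generate `n` independent study pairs plus a manifest table.

    Exactly ``round(n * cfg.gtr_fraction)`` patients (a seeded random
    subset) are gross-total resections (residual fraction 0); the others
    draw a residual fraction uniformly from ``cfg.residual_fraction_range``.

    Returns the pairs and a manifest with one row per patient:
    patient_id, true_preop_volume_mm3, true_postop_volume_mm3,
    residual_fraction, gtr_true, seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if seed is not None:
        cfg = _dc_replace(cfg, seed=int(seed))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n_gtr = int(round(n * cfg.gtr_fraction))
    gtr_patients = set(rng.choice(n, size=n_gtr, replace=False).tolist())

    pairs: list[StudyPair] = []
    rows = []
    for i in range(n):
        pid = f"P{i:03d}"
        if i in gtr_patients:
            rf = 0.0
        else:
            rf = float(rng.uniform(*cfg.residual_fraction_range))
        pair = make_phantom(cfg, pid, residual_fraction=rf)
        pairs.append(pair)
        post_count = pair.postop.mask.voxel_count()
        voxel_mm3 = float(np.prod(pair.postop.mask.spacing))
        rows.append(
            {
                "patient_id": pid,
                "true_preop_volume_mm3": pair.true_preop_volume_mm3,
                "true_postop_volume_mm3": post_count * voxel_mm3,
                "residual_fraction": pair.residual_fraction,
                "gtr_true": pair.residual_fraction == 0.0,
                "seed": cfg.seed,
            }
        )
    return pairs, pd.DataFrame(rows)
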
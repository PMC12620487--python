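"""Core/penumbra segmentation, co-registration, and mismatch volumetrics.

Thresholds follow the operational trial definitions: hypoperfusion is
Tmax strictly greater than 6 s; the ischemic core is ADC strictly below
620 x 10^-6 mm^2/s.  Mismatch volume is volume arithmetic
(hypoperfused - core, clipped at zero), not a voxelwise set difference,
matching how the DEFUSE-3 criteria are applied operationally and staying
robust to imperfect co-registration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .preprocess import BrainMask

#: conventional ischemic-core ADC threshold, mm^2/s
ADC_CORE_THRESHOLD = 620e-6
#: plausible ADC range for brain tissue, mm^2/s (unit-error guard)
ADC_PLAUSIBLE_RANGE = (0.0, 4e-3)


@dataclass
class LesionMasks:
    """Core and hypoperfusion masks on a common grid."""

    core: np.ndarray
    hypoperfusion: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core).astype(bool)
        self.hypoperfusion = np.asarray(self.hypoperfusion).astype(bool)
        if self.core.shape != self.hypoperfusion.shape:
            raise ValueError("core and hypoperfusion masks must share a grid")


@dataclass
class VolumetricSummary:
    """Lesion volumes in mL and the perfusion-diffusion mismatch.

    ``mismatch_ratio`` is +inf when there is hypoperfusion but no core
    (maximally favourable mismatch); when both volumes are zero it is
    reported as 0.0 with ``no_lesion`` set.
    """

    core_ml: float
    hypoperfused_ml: float
    mismatch_ml: float
    mismatch_ratio: float
    no_lesion: bool = False

    def as_dict(self) -> dict:
        return {
            "core_ml": self.core_ml,
            "hypoperfused_ml": self.hypoperfused_ml,
            "mismatch_ml": self.mismatch_ml,
            "mismatch_ratio": self.mismatch_ratio,
            "no_lesion": self.no_lesion,
        }


def hypoperfusion_mask(
    tmax_s: np.ndarray,
    brain: BrainMask,
    vessels: np.ndarray | None = None,
    threshold_s: float = 6.0,
) -> np.ndarray:
    """Voxels with Tmax strictly above ``threshold_s``, in brain, outside vessels."""
    if threshold_s <= 0:
        raise ValueError(f"threshold_s must be > 0, got {threshold_s}")
    out = (np.asarray(tmax_s) > threshold_s) & brain.mask
    if vessels is not None:
        out &= ~np.asarray(vessels).astype(bool)
    return out


def core_mask_from_adc(
    adc: np.ndarray,
    brain: BrainMask,
    threshold: float = ADC_CORE_THRESHOLD,
    vessels: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels with ADC strictly below ``threshold`` (mm^2/s) inside the brain.

    ADC maps are expected in mm^2/s (values around 1e-4 to 1e-3); if more
    than 10% of brain voxels fall outside the plausible tissue range the
    map was almost certainly supplied in 1e-6 units and an error is raised.
    """
    adc = np.asarray(adc, dtype=np.float64)
    inside = adc[brain.mask]
    lo, hi = ADC_PLAUSIBLE_RANGE
    with np.errstate(invalid="ignore"):
        implausible = (inside < lo) | (inside > hi)
    implausible &= np.isfinite(inside)
    if inside.size and implausible.sum() > 0.1 * inside.size:
        raise ValueError(
            "ADC values are outside the plausible tissue range [0, 4e-3] mm^2/s in "
            f"{implausible.sum()} of {inside.size} brain voxels; the map appears to be "
            "in 1e-6 mm^2/s units"
        )
    with np.errstate(invalid="ignore"):
        out = (adc < threshold) & brain.mask & np.isfinite(adc)
    if vessels is not None:
        out &= ~np.asarray(vessels).astype(bool)
    return out


def coregister(
    moving: np.ndarray,
    moving_affine: np.ndarray,
    fixed_shape: tuple[int, int, int],
    fixed_affine: np.ndarray,
    fixed_reference: np.ndarray | None = None,
    order: int = 1,
) -> np.ndarray:
    """Resample ``moving`` onto the fixed grid, optionally refining alignment.

    When the two grids already match exactly the input is returned
    unchanged (identity shortcut).  Otherwise the moving volume is
    resampled through the affines (trilinear by default).  If a
    ``fixed_reference`` image is supplied, a residual rigid translation is
    estimated by phase cross-correlation and applied.  Non-overlapping
    fields of view are an error.
    """
    moving = np.asarray(moving, dtype=np.float64)
    moving_affine = np.asarray(moving_affine, dtype=np.float64)
    fixed_affine = np.asarray(fixed_affine, dtype=np.float64)
    same_grid = tuple(moving.shape) == tuple(fixed_shape) and np.allclose(
        moving_affine, fixed_affine
    )
    if same_grid and fixed_reference is None:
        return moving

    if same_grid:
        resampled = moving
    else:
        # voxel(fixed) -> world -> voxel(moving)
        mat = np.linalg.inv(moving_affine) @ fixed_affine
        corners = np.array(
            [[i, j, k, 1.0] for i in (0, fixed_shape[0] - 1)
             for j in (0, fixed_shape[1] - 1) for k in (0, fixed_shape[2] - 1)]
        ).T
        mapped = (mat @ corners)[:3]
        inside = np.all((mapped >= -0.5) & (mapped <= np.array(moving.shape)[:, None] - 0.5), axis=0)
        if not inside.any():
            raise ValueError("non-overlapping fields of view: no fixed-grid corner maps into the moving volume")
        resampled = ndimage.affine_transform(
            moving, mat[:3, :3], offset=mat[:3, 3], output_shape=tuple(fixed_shape),
            order=order, mode="constant", cval=0.0,
        )

    if fixed_reference is not None and np.any(resampled) and np.any(fixed_reference):
        shift, _, _ = phase_cross_correlation(
            np.asarray(fixed_reference, dtype=np.float64), resampled,
            upsample_factor=10, normalization=None,
        )
        if np.linalg.norm(shift) >= 0.1:
            resampled = ndimage.shift(resampled, shift, order=order, mode="constant", cval=0.0)
        elif same_grid:
            return moving
    return resampled


def volumes(masks: LesionMasks) -> VolumetricSummary:
    """Mask voxel counts converted to mL, with mismatch volume and ratio."""
    dx, dy, dz = masks.voxel_mm
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"voxel spacing must be positive, got {masks.voxel_mm}")
    voxel_ml = dx * dy * dz / 1000.0
    core_ml = float(masks.core.sum() * voxel_ml)
    hypo_ml = float(masks.hypoperfusion.sum() * voxel_ml)
    mismatch_ml = max(hypo_ml - core_ml, 0.0)
    if core_ml > 0:
        ratio = hypo_ml / core_ml
        no_lesion = False
    elif hypo_ml > 0:
        ratio = math.inf
        no_lesion = False
    else:
        ratio = 0.0
        no_lesion = True
    return VolumetricSummary(
        core_ml=core_ml,
        hypoperfused_ml=hypo_ml,
        mismatch_ml=mismatch_ml,
        mismatch_ratio=ratio,
        no_lesion=no_lesion,
    )
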
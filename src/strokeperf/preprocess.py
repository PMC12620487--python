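"""Motion correction, brain extraction, and vessel masking.

Motion is modelled as a per-frame 3-D translation estimated by phase
cross-correlation against the temporal-mean reference; sub-0.1-voxel shifts
are left untouched so correction is exactly idempotent on static series.
Brain extraction is deliberately simple and deterministic: Otsu threshold on
the temporal mean, morphological closing, largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from skimage.registration import phase_cross_correlation

from .io import PerfusionStudy

#: shifts below this many voxels are treated as zero (no resampling)
MIN_SHIFT_VOXELS = 0.1


@dataclass
class BrainMask:
    """Binary brain mask on the study grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("brain mask must be 3D")
        vals = np.unique(self.mask)
        if not set(vals.tolist()) <= {0, 1, False, True}:
            raise ValueError("mask values must be in {0, 1}")
        self.mask = self.mask.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def correct_motion(
    study: PerfusionStudy,
    upsample_factor: int = 10,
) -> tuple[PerfusionStudy, pd.DataFrame]:
    """Rigidly (translation) align each frame to the temporal-mean reference.

    Returns the corrected study and a per-timepoint report with the applied
    shift (voxels), its magnitude in mm, and a divergence flag.  A frame
    whose estimated shift exceeds a quarter of the field of view is flagged
    as diverged and returned uncorrected.
    """
    if study.n_time < 2:
        raise ValueError("motion correction needs at least 2 timepoints")
    signal = study.signal
    reference = signal.mean(axis=3)
    voxel = np.asarray(study.voxel_mm)
    max_reasonable = np.asarray(signal.shape[:3]) / 4.0

    corrected = np.empty_like(signal)
    rows = []
    for t in range(study.n_time):
        frame = signal[..., t]
        if not frame.any() or not reference.any():
            shift = np.zeros(3)
        else:
            shift, _, _ = phase_cross_correlation(
                reference, frame, upsample_factor=upsample_factor, normalization=None
            )
        diverged = bool(np.any(np.abs(shift) > max_reasonable))
        if diverged or np.linalg.norm(shift) < MIN_SHIFT_VOXELS:
            corrected[..., t] = frame
            applied = np.zeros(3) if not diverged else shift
        else:
            corrected[..., t] = ndimage.shift(frame, shift, order=1, mode="constant", cval=0.0)
            applied = shift
        rows.append(
            {
                "timepoint": t,
                "dx_mm": applied[0] * voxel[0],
                "dy_mm": applied[1] * voxel[1],
                "dz_mm": applied[2] * voxel[2],
                "displacement_mm": float(np.linalg.norm(applied * voxel)),
                "diverged": diverged,
            }
        )
    report = pd.DataFrame(rows)
    out = PerfusionStudy(
        signal=np.clip(corrected, 0.0, None),
        tr_s=study.tr_s,
        te_s=study.te_s,
        voxel_mm=study.voxel_mm,
        affine=study.affine,
        adc=study.adc,
        adc_affine=study.adc_affine,
        patient=study.patient,
    )
    return out, report


def skull_strip(study: PerfusionStudy, closing_radius: int = 3) -> BrainMask:
    """Extract the brain as the largest component of the thresholded temporal mean."""
    mean_img = study.signal.mean(axis=3)
    if not np.any(mean_img > 0):
        raise ValueError("empty foreground: temporal mean image is all zero")
    lo, hi = float(mean_img.min()), float(mean_img.max())
    if lo == hi:
        # uniform nonzero image: everything is foreground
        return BrainMask(np.ones(mean_img.shape, dtype=bool))
    thr = threshold_otsu(mean_img)
    fg = mean_img > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    # zero-pad before closing so the operator stays extensive at the borders
    r = closing_radius
    padded = np.pad(fg, r)
    padded = ndimage.binary_closing(padded, structure=ball(r))
    fg = padded[r:-r, r:-r, r:-r] | fg
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return BrainMask(fg)


def vessel_mask(cbv_like: np.ndarray, brain: BrainMask, percentile: float = 0.99) -> np.ndarray:
    """Flag brain voxels strictly above the given upper quantile of in-brain values.

    Large vessels carry disproportionate contrast; they are excluded from
    lesion statistics downstream.  Ties at the quantile are not flagged
    (strict inequality), so a constant field yields an empty mask.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    if brain.n_voxels == 0:
        raise ValueError("empty brain mask")
    cbv_like = np.asarray(cbv_like, dtype=np.float64)
    inside = cbv_like[brain.mask]
    q = np.quantile(inside, percentile)
    return (cbv_like > q) & brain.mask
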
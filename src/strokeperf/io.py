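"""Volumetric I/O and the validated in-memory study container.

All on-disk volumes are NIfTI-1 (``.nii``/``.nii.gz``); acquisition timing
(TR/TE), which NIfTI does not carry reliably, comes from a JSON sidecar with
keys ``tr_s`` and ``te_s``.  Every downstream module consumes the in-memory
types defined here; no other module touches the filesystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


class OcclusionSite(str, Enum):
    """Occlusion site categories used by the eligibility gates."""

    ANTERIOR_LVO = "anterior_lvo"
    BASILAR = "basilar"
    NONE = "none"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PatientProfile:
    """Clinical fields needed for trial-eligibility gating.

    Parameters
    ----------
    age_years : int
        Age at presentation, years.
    nihss : int
        NIH Stroke Scale score, 0-42.
    occlusion_site : OcclusionSite
        Site of the arterial occlusion on MR angiography.
    """

    age_years: int
    nihss: int
    occlusion_site: OcclusionSite = OcclusionSite.UNKNOWN

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        if not 0 <= self.nihss <= 42:
            raise ValueError(f"nihss must be within 0-42, got {self.nihss}")
        if not isinstance(self.occlusion_site, OcclusionSite):
            object.__setattr__(self, "occlusion_site", OcclusionSite(self.occlusion_site))


@dataclass
class PerfusionStudy:
    """A dynamic susceptibility contrast acquisition plus metadata.

    ``signal`` is the raw 4-D MR magnitude series (x, y, z, t) in arbitrary
    scanner units; ``adc`` optionally carries an apparent-diffusion-
    coefficient map in mm^2/s for core estimation.
    """

    signal: np.ndarray
    tr_s: float
    te_s: float
    voxel_mm: tuple[float, float, float]
    affine: Optional[np.ndarray] = None
    adc: Optional[np.ndarray] = None
    adc_affine: Optional[np.ndarray] = None
    patient: Optional[PatientProfile] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 4:
            raise ValueError(f"expected 4D series, got {self.signal.ndim}D")
        if any(d < 1 for d in self.signal.shape):
            raise ValueError(f"all signal dimensions must be >= 1, got {self.signal.shape}")
        if self.signal.shape[3] < 20:
            raise ValueError(
                f"need >= 20 time frames for bolus tracking, got {self.signal.shape[3]}"
            )
        if not 0.5 < self.tr_s <= 3.0:
            raise ValueError(f"tr_s must be in (0.5, 3.0] s, got {self.tr_s}")
        if not 0.01 < self.te_s <= 0.1:
            raise ValueError(f"te_s must be in (0.01, 0.1] s, got {self.te_s}")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be three positive spacings, got {self.voxel_mm}")
        if np.nanmin(self.signal) < 0:
            raise ValueError("signal values must be >= 0")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.adc is not None:
            self.adc = np.asarray(self.adc, dtype=np.float64)
            if self.adc.ndim != 3:
                raise ValueError(f"adc map must be 3D, got {self.adc.ndim}D")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.signal.shape

    @property
    def n_time(self) -> int:
        return self.signal.shape[3]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _spacing_from_header(img: nib.Nifti1Image, n: int = 3) -> tuple[float, ...]:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:n])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    return zooms


def read_series(
    path: str | Path,
    sidecar: str | Path | None = None,
    adc_path: str | Path | None = None,
    patient: PatientProfile | None = None,
) -> PerfusionStudy:
    """Read a 4-D DSC series (and optional ADC map) into a validated study.

    TR/TE must be supplied by a JSON sidecar (``{"tr_s": ..., "te_s": ...}``);
    by default it is looked up next to the series file.  Any invariant
    violation raises rather than warns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series, got {data.ndim}D")
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"TR/TE sidecar not found: {sidecar} (required; no silent defaults)"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("tr_s", "te_s"):
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} missing required key '{key}'")
    adc = adc_affine = None
    if adc_path is not None:
        adc, _, adc_affine = read_scalar_map(adc_path)
    return PerfusionStudy(
        signal=data,
        tr_s=float(meta["tr_s"]),
        te_s=float(meta["te_s"]),
        voxel_mm=_spacing_from_header(img),
        affine=np.asarray(img.affine),
        adc=adc,
        adc_affine=adc_affine,
        patient=patient,
    )


def read_scalar_map(
    path: str | Path,
    reference_shape: Sequence[int] | None = None,
) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Read a 3-D scalar map; returns (values, spacing_mm, affine).

    NaN voxels are preserved.  If ``reference_shape`` is given, a dimension
    mismatch is an error (co-registration lives in :mod:`strokeperf.lesions`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"map file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D map, got {data.ndim}D")
    if reference_shape is not None and tuple(data.shape) != tuple(reference_shape):
        raise ValueError(
            f"map shape {data.shape} does not match reference grid {tuple(reference_shape)}"
        )
    return data, _spacing_from_header(img), np.asarray(img.affine)


def write_map(
    field_: np.ndarray,
    spacing: Sequence[float],
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write a 3-D scalar field or mask as NIfTI-1.

    Binary {0,1} fields are stored as unsigned 8-bit; everything else as
    float64 so round-trips are bitwise.
    """
    field_ = np.asarray(field_)
    finite = field_[np.isfinite(field_)]
    if finite.size and not np.isfinite(finite).all():  # pragma: no cover - defensive
        raise ValueError("field contains non-finite, non-NaN values")
    if affine is None:
        affine = np.diag([*spacing, 1.0])
    is_mask = field_.dtype == bool or (
        np.issubdtype(field_.dtype, np.integer) and finite.size and set(np.unique(field_)) <= {0, 1}
    )
    out = field_.astype(np.uint8) if is_mask else field_.astype(np.float64)
    img = nib.Nifti1Image(out, np.asarray(affine, dtype=np.float64))
    img.header.set_zooms(tuple(float(s) for s in spacing[: field_.ndim]))
    nib.save(img, str(path))


def write_series(study: PerfusionStudy, path: str | Path) -> None:
    """Write a study's 4-D signal plus its TR/TE sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(study.signal.astype(np.float64), study.affine)
    img.header.set_zooms((*study.voxel_mm, float(study.tr_s)))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"tr_s": study.tr_s, "te_s": study.te_s}))


def read_patient_profiles(path: str | Path) -> dict[str, PatientProfile]:
    """Read patient profiles from CSV (columns id, age_years, nihss, occlusion_site)."""
    df = pd.read_csv(path)
    required = {"id", "age_years", "nihss", "occlusion_site"}
    if missing := required - set(df.columns):
        raise ValueError(f"patient CSV missing columns: {sorted(missing)}")
    return {
        str(row.id): PatientProfile(
            age_years=int(row.age_years),
            nihss=int(row.nihss),
            occlusion_site=OcclusionSite(row.occlusion_site),
        )
        for row in df.itertuples()
    }
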
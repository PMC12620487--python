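"""Model-style front end: a perfusion study in, fitted results out.

:class:`DscPerfusion` bundles the whole tracer-kinetic analysis --
preprocessing, concentration conversion, AIF selection, block-circulant SVD
deconvolution, lesion thresholding, volumetrics and (when clinical fields
are present) trial eligibility -- behind a ``fit()`` call that returns a
:class:`DscPerfusionResults` carrying maps, masks, diagnostics and a
``summary()`` table, and that can persist everything to disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._version import __version__ as _VERSION
from .config import RunConfig
from .deconvolution import PerfusionMaps, compute_maps, deconvolve_csvd
from .eligibility import EligibilityResult, classify_dawn, classify_defuse3
from .io import PerfusionStudy, write_map
from .kinetics import (
    ConcentrationSeries,
    InputFunction,
    detect_bolus_arrival,
    select_aif,
    select_vof,
    signal_to_concentration,
)
from .lesions import LesionMasks, VolumetricSummary, coregister, core_mask_from_adc, hypoperfusion_mask, volumes
from .preprocess import BrainMask, correct_motion, skull_strip, vessel_mask


class DscPerfusion:
    """Dynamic-susceptibility-contrast perfusion model for one study.

    Parameters
    ----------
    study : PerfusionStudy
        Validated 4-D acquisition (see :func:`strokeperf.io.read_series`).
    config : RunConfig, optional
        Analysis thresholds; defaults are the trial-standard values.

    Examples
    --------
    >>> model = DscPerfusion(study)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, study: PerfusionStudy, config: RunConfig | None = None) -> None:
        self.study = study
        self.config = config or RunConfig()

    def fit(self, motion_correct: bool = True) -> "DscPerfusionResults":
        cfg = self.config
        study = self.study
        if motion_correct:
            study, motion = correct_motion(study)
        else:
            motion = pd.DataFrame()

        brain = skull_strip(study)
        mean_curve = study.signal[brain.mask].mean(axis=0)
        t0 = detect_bolus_arrival(
            mean_curve, k_sd=cfg.bolus_k_sd, baseline_frames=cfg.baseline_frames
        )
        conc = signal_to_concentration(study, brain, t0)
        aif = select_aif(conc, brain, n_select=cfg.aif_n)
        vof = None
        try:
            vof = select_vof(conc, brain, n_select=cfg.aif_n)
        except ValueError:
            pass

        k_field = deconvolve_csvd(conc, aif, threshold_frac=cfg.svd_threshold_frac, brain=brain)
        maps = compute_maps(k_field, conc, aif, brain, study.voxel_mm)

        vessels = vessel_mask(maps.cbv, brain, percentile=cfg.vessel_percentile)
        hypo = hypoperfusion_mask(maps.tmax_s, brain, vessels, threshold_s=cfg.tmax_threshold_s)

        core = np.zeros(brain.mask.shape, dtype=bool)
        if study.adc is not None:
            adc = study.adc
            if adc.shape != brain.mask.shape:
                adc = coregister(
                    adc,
                    study.adc_affine if study.adc_affine is not None else study.affine,
                    brain.mask.shape,
                    study.affine,
                )
            core = core_mask_from_adc(adc, brain, threshold=cfg.adc_threshold, vessels=vessels)

        masks = LesionMasks(core=core, hypoperfusion=hypo, voxel_mm=study.voxel_mm)
        summary = volumes(masks)

        eligibility: dict[str, EligibilityResult] = {}
        if study.patient is not None:
            eligibility["dawn"] = classify_dawn(
                study.patient, summary.core_ml, cutoffs_ml=cfg.dawn_cutoffs_ml
            )
            eligibility["defuse3"] = classify_defuse3(
                study.patient,
                summary,
                core_max_ml=cfg.defuse3_core_max_ml,
                ratio_min=cfg.defuse3_ratio_min,
                mismatch_min_ml=cfg.defuse3_mismatch_min_ml,
            )

        return DscPerfusionResults(
            model=self,
            study=study,
            motion=motion,
            brain=brain,
            vessels=vessels,
            conc=conc,
            aif=aif,
            vof=vof,
            maps=maps,
            lesion_masks=masks,
            volumetrics=summary,
            eligibility=eligibility,
        )


@dataclass
class DscPerfusionResults:
    """Fitted perfusion maps, lesion masks, volumetrics, and eligibility."""

    model: DscPerfusion
    study: PerfusionStudy
    motion: pd.DataFrame
    brain: BrainMask
    vessels: np.ndarray
    conc: ConcentrationSeries
    aif: InputFunction
    vof: Optional[InputFunction]
    maps: PerfusionMaps
    lesion_masks: LesionMasks
    volumetrics: VolumetricSummary
    eligibility: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        return {
            "software": "strokeperf",
            "version": _VERSION,
            "config": self.model.config.as_dict(),
            "bolus_arrival_frame": self.conc.t0_index,
            "aif_fit_converged": bool(
                self.aif.fit_params is not None and self.aif.fit_params.converged
            ),
            "n_aif_voxels": int(self.aif.voxel_ids.size),
            "max_displacement_mm": (
                float(self.motion["displacement_mm"].max()) if len(self.motion) else 0.0
            ),
            "deconvolution": self.maps.diagnostics,
        }

    def summary_dict(self) -> dict:
        out = {
            "volumes": self.volumetrics.as_dict(),
            "eligibility": {
                trial: {
                    "in_population": res.in_population,
                    "eligible": res.eligible,
                    "stratum": res.stratum.value,
                    "reasons": res.reasons,
                }
                for trial, res in self.eligibility.items()
            },
            "provenance": self.provenance(),
        }
        return out

    def summary(self) -> str:
        v = self.volumetrics
        ratio = "inf" if v.mismatch_ratio == float("inf") else f"{v.mismatch_ratio:.2f}"
        lines = [
            "DSC perfusion analysis summary",
            f"  grid: {self.study.shape} @ {self.study.voxel_mm} mm, TR {self.study.tr_s} s",
            f"  brain voxels: {self.brain.n_voxels}; vessel-excluded: {int(self.vessels.sum())}",
            f"  bolus arrival frame: {self.conc.t0_index}",
            f"  ischemic core:      {v.core_ml:8.1f} mL",
            f"  hypoperfused (Tmax>{self.model.config.tmax_threshold_s:g}s): {v.hypoperfused_ml:8.1f} mL",
            f"  mismatch volume:    {v.mismatch_ml:8.1f} mL  (ratio {ratio})",
        ]
        for trial, res in self.eligibility.items():
            verdict = "eligible" if res.eligible else ("ineligible" if res.in_population else "not in population")
            extra = f" [{', '.join(res.reasons)}]" if res.reasons else ""
            lines.append(f"  {trial.upper()}: {verdict}{extra}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write maps, masks, motion report, and the summary/provenance JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spacing = self.study.voxel_mm
        affine = self.study.affine
        for name, arr in (
            ("cbf", self.maps.cbf),
            ("cbv", self.maps.cbv),
            ("mtt_s", self.maps.mtt_s),
            ("tmax_s", self.maps.tmax_s),
        ):
            write_map(arr, spacing, outdir / f"{name}.nii.gz", affine=affine)
        for name, arr in (
            ("brain_mask", self.brain.mask.astype(np.uint8)),
            ("vessel_mask", self.vessels.astype(np.uint8)),
            ("core_mask", self.lesion_masks.core.astype(np.uint8)),
            ("hypoperfusion_mask", self.lesion_masks.hypoperfusion.astype(np.uint8)),
        ):
            write_map(arr, spacing, outdir / f"{name}.nii.gz", affine=affine)
        if len(self.motion):
            self.motion.to_csv(outdir / "motion.csv", index=False)
        aif_df = pd.DataFrame(
            {
                "frame": np.arange(self.aif.curve.size),
                "seconds": np.arange(self.aif.curve.size) * self.aif.tr_s,
                "concentration": self.aif.curve,
                "fitted": (
                    self.aif.fitted_curve
                    if self.aif.fitted_curve is not None
                    else np.full(self.aif.curve.size, np.nan)
                ),
            }
        )
        aif_df.to_csv(outdir / "aif.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.summary_dict(), indent=2, sort_keys=True))
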
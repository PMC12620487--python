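"""Endovascular-therapy eligibility under DAWN and DEFUSE-3 imaging criteria.

Only the imaging-and-clinical gating actually exercised by inter-platform
comparison is implemented: population gates (NIHSS floor + anterior
large-vessel occlusion), the DAWN clinical-core-mismatch strata with their
core-volume cutoffs, and the DEFUSE-3 perfusion-mismatch rule
(core < 70 mL, mismatch ratio >= 1.8, mismatch volume >= 15 mL).  Time-
window clocks and pre-stroke mRS gating are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Mapping

from .agreement import ContingencyTable
from .io import OcclusionSite, PatientProfile
from .lesions import VolumetricSummary

#: DAWN per-stratum core-volume cutoffs (mL), strict '<'
DAWN_CORE_CUTOFFS_ML = (21.0, 31.0, 51.0)

DEFUSE3_CORE_MAX_ML = 70.0
DEFUSE3_MISMATCH_RATIO_MIN = 1.8
DEFUSE3_MISMATCH_MIN_ML = 15.0


class Trial(str, Enum):
    DAWN = "DAWN"
    DEFUSE3 = "DEFUSE3"


class DawnStratum(str, Enum):
    """DAWN age/NIHSS strata (the study's boundaries: '>80' vs '<=80')."""

    A_GT80_NIHSS_GE10 = "age_gt80_nihss_ge10"
    B_LE80_NIHSS_10_19 = "age_le80_nihss_10_19"
    C_LE80_NIHSS_GE20 = "age_le80_nihss_ge20"
    NONE = "none"


@dataclass
class EligibilityResult:
    trial: Trial
    in_population: bool
    eligible: bool
    stratum: DawnStratum = DawnStratum.NONE
    reasons: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eligible and not self.in_population:
            raise ValueError("eligible implies in_population")
        if self.stratum != DawnStratum.NONE and self.trial != Trial.DAWN:
            raise ValueError("strata apply to DAWN only")


def _dawn_stratum(profile: PatientProfile) -> DawnStratum:
    if profile.nihss < 10:
        return DawnStratum.NONE
    if profile.age_years > 80:
        return DawnStratum.A_GT80_NIHSS_GE10
    if profile.nihss <= 19:
        return DawnStratum.B_LE80_NIHSS_10_19
    return DawnStratum.C_LE80_NIHSS_GE20


def classify_dawn(
    profile: PatientProfile,
    core_ml: float,
    cutoffs_ml: tuple[float, float, float] = DAWN_CORE_CUTOFFS_ML,
) -> EligibilityResult:
    """DAWN clinical-core-mismatch eligibility.

    Population gate: NIHSS >= 10 and anterior-circulation LVO.  Within the
    gate each patient falls in exactly one age/NIHSS stratum and is eligible
    iff the infarct core is strictly below the stratum's cutoff.
    """
    if core_ml < 0:
        raise ValueError(f"core_ml must be >= 0, got {core_ml}")
    if profile.occlusion_site == OcclusionSite.UNKNOWN:
        return EligibilityResult(Trial.DAWN, False, False, reasons=["site_unknown"])
    in_pop = profile.nihss >= 10 and profile.occlusion_site == OcclusionSite.ANTERIOR_LVO
    if not in_pop:
        return EligibilityResult(Trial.DAWN, False, False)
    stratum = _dawn_stratum(profile)
    cutoff = {
        DawnStratum.A_GT80_NIHSS_GE10: cutoffs_ml[0],
        DawnStratum.B_LE80_NIHSS_10_19: cutoffs_ml[1],
        DawnStratum.C_LE80_NIHSS_GE20: cutoffs_ml[2],
    }[stratum]
    eligible = core_ml < cutoff
    reasons = [] if eligible else [f"core_ge_{cutoff:g}"]
    return EligibilityResult(Trial.DAWN, True, eligible, stratum=stratum, reasons=reasons)


def classify_defuse3(
    profile: PatientProfile,
    summary: VolumetricSummary,
    core_max_ml: float = DEFUSE3_CORE_MAX_ML,
    ratio_min: float = DEFUSE3_MISMATCH_RATIO_MIN,
    mismatch_min_ml: float = DEFUSE3_MISMATCH_MIN_ML,
) -> EligibilityResult:
    """DEFUSE-3 perfusion-mismatch eligibility.

    Population gate: NIHSS >= 6 and anterior-circulation LVO.  Eligible iff
    core < 70 mL AND mismatch ratio >= 1.8 AND mismatch volume >= 15 mL;
    every failed criterion is reported.
    """
    if profile.occlusion_site == OcclusionSite.UNKNOWN:
        return EligibilityResult(Trial.DEFUSE3, False, False, reasons=["site_unknown"])
    in_pop = profile.nihss >= 6 and profile.occlusion_site == OcclusionSite.ANTERIOR_LVO
    if not in_pop:
        return EligibilityResult(Trial.DEFUSE3, False, False)
    reasons = []
    if not summary.core_ml < core_max_ml:
        reasons.append(f"core_ge_{core_max_ml:g}")
    if not summary.mismatch_ratio >= ratio_min:
        reasons.append(f"ratio_lt_{ratio_min:g}")
    if not summary.mismatch_ml >= mismatch_min_ml:
        reasons.append(f"mismatch_lt_{mismatch_min_ml:g}")
    return EligibilityResult(Trial.DEFUSE3, True, not reasons, reasons=reasons)


def classify_cohort(
    df,
    trial: Trial | str,
    platform: str,
    cutoffs_ml: tuple[float, float, float] = DAWN_CORE_CUTOFFS_ML,
) -> dict[str, EligibilityResult]:
    """Classify every patient in a tidy cohort frame for one platform.

    The frame needs columns ``id``, ``age_years``, ``nihss``,
    ``occlusion_site`` and ``{platform}_core_ml`` (DAWN) plus
    ``{platform}_hypoperfused_ml`` (DEFUSE-3).
    """
    trial = Trial(trial) if not isinstance(trial, Trial) else trial
    out: dict[str, EligibilityResult] = {}
    for row in df.itertuples():
        profile = PatientProfile(
            int(row.age_years), int(row.nihss), OcclusionSite(row.occlusion_site)
        )
        core = float(getattr(row, f"{platform}_core_ml"))
        if trial == Trial.DAWN:
            out[str(row.id)] = classify_dawn(profile, core, cutoffs_ml=cutoffs_ml)
        else:
            hypo = float(getattr(row, f"{platform}_hypoperfused_ml"))
            mismatch = max(hypo - core, 0.0)
            ratio = hypo / core if core > 0 else (float("inf") if hypo > 0 else 0.0)
            summary = VolumetricSummary(
                core_ml=core,
                hypoperfused_ml=hypo,
                mismatch_ml=mismatch,
                mismatch_ratio=ratio,
                no_lesion=(core == 0 and hypo == 0),
            )
            out[str(row.id)] = classify_defuse3(profile, summary)
    return out


def tabulate_eligibility(
    results_a: Mapping[str, EligibilityResult],
    results_b: Mapping[str, EligibilityResult],
) -> dict[str, ContingencyTable]:
    """Cross-tabulate paired eligibility verdicts into 2x2 tables.

    ``results_a`` (rows) and ``results_b`` (columns) map patient id to the
    verdict from each platform.  Only patients in the trial population are
    counted; because the gate is purely clinical it must agree between
    platforms.  Returns a table under ``"all"`` plus, for DAWN, one table
    per stratum.
    """
    if set(results_a) != set(results_b):
        odd = set(results_a) ^ set(results_b)
        raise ValueError(f"unpaired patient ids: {sorted(odd)[:5]}{'...' if len(odd) > 5 else ''}")

    def make_table(ids) -> ContingencyTable:
        cells = [[0, 0], [0, 0]]
        for pid in ids:
            ra, rb = results_a[pid], results_b[pid]
            cells[int(ra.eligible)][int(rb.eligible)] += 1
        return ContingencyTable(cells)

    pop_ids = sorted(pid for pid in results_a if results_a[pid].in_population)
    mismatched_gate = [p for p in pop_ids if not results_b[p].in_population]
    if mismatched_gate:
        raise ValueError(f"population gate disagrees between platforms for ids {mismatched_gate[:5]}")
    if not pop_ids:
        warnings.warn("no in-population patients; returning an all-zero table", stacklevel=2)
        return {"all": ContingencyTable([[0, 0], [0, 0]])}

    tables = {"all": make_table(pop_ids)}
    if results_a[pop_ids[0]].trial == Trial.DAWN:
        for stratum in (
            DawnStratum.A_GT80_NIHSS_GE10,
            DawnStratum.B_LE80_NIHSS_10_19,
            DawnStratum.C_LE80_NIHSS_GE20,
        ):
            ids = [p for p in pop_ids if results_a[p].stratum == stratum]
            if ids:
                tables[stratum.value] = make_table(ids)
    return tables
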
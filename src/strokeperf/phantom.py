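"""Digital phantoms with known ground truth for every pipeline stage.

Three generators:

* :func:`make_study` -- a 4-D bolus-tracking acquisition built from
  gamma-variate arterial kinetics.  Per tissue voxel the concentration is
  ``(cbf/100) * TR * (AIF conv R)(t - delay)`` with an exponential residue
  ``R(t) = exp(-t / mtt)``; flow is therefore in relative units where the
  generator's ``cbf`` parameter is recovered as ``100 * max_t k(t)``.
  Signal is ``s0 * exp(-TE * C(t))`` plus seeded Gaussian noise, clipped at
  zero.  An ADC map with a planted low-diffusivity core lesion accompanies
  the series.
* :func:`make_paired_cohort` -- paired per-patient volumes emulating two
  platforms measuring the same true (log-normal) volumes with multiplicative
  log-normal platform error; the error SD can be calibrated in closed form
  to hit a target concordance correlation.
* :func:`make_eligibility_cohort` -- "target-table mode": a cohort whose
  per-platform eligibility verdicts realize an exact 2x2 contingency table.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import OcclusionSite, PatientProfile, PerfusionStudy
from .kinetics import gamma_variate

#: ADC values planted by the phantom, mm^2/s
ADC_LESION = 500e-6
ADC_BACKGROUND = 800e-6


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus parameters: A * (t - t0)^alpha * exp(-(t - t0)/beta)."""

    amplitude: float = 1.102  # peak concentration ~5 relative units
    onset_s: float = 10.0
    alpha: float = 3.0
    beta_s: float = 1.5

    def __post_init__(self) -> None:
        if min(self.amplitude, self.alpha, self.beta_s) < 0:
            raise ValueError("gamma-variate parameters must be non-negative")


@dataclass
class TissueRegion:
    """A region of homogeneous kinetics.

    ``mask`` is a 3-D boolean field; ``cbf`` is relative flow (recovered as
    100 * max k), ``mtt_s`` the mean transit time, ``delay_s`` the bolus
    arrival delay (discretized to the TR grid), ``is_core`` marks the
    planted diffusion lesion.
    """

    mask: np.ndarray
    cbf: float
    mtt_s: float
    delay_s: float = 0.0
    is_core: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.cbf <= 0 or self.mtt_s <= 0:
            raise ValueError("cbf and mtt_s must be > 0")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition."""

    shape: tuple[int, int, int] = (64, 64, 10)
    voxel_mm: tuple[float, float, float] = (3.4, 3.4, 5.0)
    n_time: int = 60
    tr_s: float = 1.5
    te_s: float = 0.04
    aif: AifParams = field(default_factory=AifParams)
    regions: list[TissueRegion] = field(default_factory=list)
    vessel_mask: np.ndarray | None = None
    noise_sd: float = 1.0
    s0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        occupancy = np.zeros(self.shape, dtype=np.int32)
        for r in self.regions:
            if r.mask.shape != tuple(self.shape):
                raise ValueError("region mask shape does not match the grid")
            occupancy += r.mask
        if (occupancy > 1).any():
            raise ValueError("tissue regions must be disjoint")


@dataclass
class GroundTruth:
    """Voxelwise truth accompanying a phantom study."""

    cbf: np.ndarray
    mtt_s: np.ndarray
    delay_s: np.ndarray
    concentration: np.ndarray
    tissue_mask: np.ndarray
    core_mask: np.ndarray
    hypoperfusion_mask: np.ndarray
    vessel_mask: np.ndarray
    adc: np.ndarray
    aif_curve: np.ndarray


def make_aif(params: AifParams, n_time: int, tr_s: float) -> np.ndarray:
    """Sample the gamma-variate bolus on the TR grid."""
    if params.onset_s >= n_time * tr_s:
        raise ValueError(
            f"bolus onset {params.onset_s}s is beyond the {n_time * tr_s}s series"
        )
    t = np.arange(n_time) * tr_s
    return gamma_variate(t, params.amplitude, params.onset_s, params.alpha, params.beta_s)


def ellipsoid_mask(
    shape: Sequence[int],
    center: Sequence[float],
    semiaxes: Sequence[float],
) -> np.ndarray:
    """Boolean ellipsoid on a voxel grid (axes in voxel units)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def default_spec(seed: int = 0, noise_sd: float = 1.0) -> PhantomSpec:
    """The standard test phantom: healthy tissue plus a delayed lesion.

    A large tissue ellipsoid (CBF 60, MTT 4 s, no delay) contains a
    hypoperfused sphere (CBF 20, MTT 10 s, delay 9 s) with a smaller
    diffusion-restricted core inside it, and a short line of high-signal
    vessel voxels near the centre.
    """
    shape = (64, 64, 10)
    brain = ellipsoid_mask(shape, (31.5, 31.5, 4.5), (28, 28, 4.4))
    lesion = ellipsoid_mask(shape, (44, 32, 4.5), (8, 8, 2.4)) & brain
    core = ellipsoid_mask(shape, (44, 32, 4.5), (4, 4, 1.6)) & brain
    vessels = np.zeros(shape, dtype=bool)
    vessels[28:34, 14, 4:6] = True
    healthy = brain & ~lesion & ~vessels
    regions = [
        TissueRegion(mask=healthy, cbf=60.0, mtt_s=4.0, delay_s=0.0),
        TissueRegion(mask=lesion & ~core & ~vessels, cbf=20.0, mtt_s=10.0, delay_s=9.0),
        TissueRegion(mask=core & ~vessels, cbf=20.0, mtt_s=10.0, delay_s=9.0, is_core=True),
    ]
    return PhantomSpec(shape=shape, regions=regions, vessel_mask=vessels, noise_sd=noise_sd, seed=seed)


def multilevel_spec(seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """A graded-flow phantom: parallel slabs spanning CBF 20..60.

    Slabs alternate MTT between 4 and 10 s and the low-flow half carries a
    9 s arrival delay, exercising rank recovery across the full parameter
    grid.
    """
    shape = (64, 64, 10)
    brain = ellipsoid_mask(shape, (31.5, 31.5, 4.5), (28, 28, 4.4))
    vessels = np.zeros(shape, dtype=bool)
    vessels[28:34, 8, 4:6] = True
    levels = [20.0, 30.0, 40.0, 50.0, 60.0]
    regions = []
    xs = np.arange(shape[0])
    for i, cbf in enumerate(levels):
        band = (xs[:, None, None] >= 4 + i * 11) & (xs[:, None, None] < 4 + (i + 1) * 11)
        mask = brain & np.broadcast_to(band, shape) & ~vessels
        regions.append(
            TissueRegion(
                mask=mask,
                cbf=cbf,
                mtt_s=4.0 if i % 2 == 0 else 10.0,
                delay_s=9.0 if cbf < 40 else 0.0,
            )
        )
    return PhantomSpec(shape=shape, regions=regions, vessel_mask=vessels, noise_sd=noise_sd, seed=seed)


def make_study(spec: PhantomSpec) -> tuple[PerfusionStudy, GroundTruth]:
    """Render a phantom specification into a study plus its ground truth."""
    nt, tr = spec.n_time, spec.tr_s
    aif = make_aif(spec.aif, nt, tr)

    conc = np.zeros((*spec.shape, nt))
    cbf_map = np.zeros(spec.shape)
    mtt_map = np.zeros(spec.shape)
    delay_map = np.zeros(spec.shape)
    tissue = np.zeros(spec.shape, dtype=bool)
    core = np.zeros(spec.shape, dtype=bool)

    # residue sampled on the padded grid so delayed kernels never truncate
    j = np.arange(2 * nt) * tr
    for region in spec.regions:
        if not region.mask.any():
            continue
        residue = np.exp(-j / region.mtt_s)
        kernel = tr * np.convolve(aif, residue)[:nt] * (region.cbf / 100.0)
        d_frames = round(region.delay_s / tr)
        curve = np.zeros(nt)
        if d_frames < nt:
            curve[d_frames:] = kernel[: nt - d_frames]
        conc[region.mask] = curve
        cbf_map[region.mask] = region.cbf
        mtt_map[region.mask] = region.mtt_s
        delay_map[region.mask] = region.delay_s
        tissue |= region.mask
        if region.is_core:
            core |= region.mask

    vessels = (
        spec.vessel_mask.astype(bool)
        if spec.vessel_mask is not None
        else np.zeros(spec.shape, dtype=bool)
    )
    conc[vessels] = 3.0 * aif
    tissue |= vessels

    signal = np.where(tissue[..., None], spec.s0 * np.exp(-spec.te_s * conc), 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    signal = np.clip(signal, 0.0, None)

    adc = np.zeros(spec.shape)
    adc[tissue] = ADC_BACKGROUND
    adc[core] = ADC_LESION

    study = PerfusionStudy(
        signal=signal,
        tr_s=tr,
        te_s=spec.te_s,
        voxel_mm=spec.voxel_mm,
        adc=adc,
    )
    truth = GroundTruth(
        cbf=cbf_map,
        mtt_s=mtt_map,
        delay_s=delay_map,
        concentration=conc,
        tissue_mask=tissue,
        core_mask=core,
        hypoperfusion_mask=(delay_map > 6.0) & tissue & ~vessels,
        vessel_mask=vessels,
        adc=adc,
        aif_curve=aif,
    )
    return study, truth


# ---------------------------------------------------------------------------
# paired-platform cohort generators
# ---------------------------------------------------------------------------

def calibrate_error_sd(volume_log_sd: float, target_ccc: float, error_corr: float = 0.0) -> float:
    """Log-scale platform-error SD that yields ``target_ccc`` in closed form.

    For log-normal true volumes (log-SD ``s_v``) observed by two platforms
    with independent multiplicative log-normal errors (log-SD ``s_e``),
    CCC = (exp(s_v^2) - 1) / (exp(s_v^2 + s_e^2) - 1); correlated errors
    (``error_corr``) raise the numerator's exponent by ``rho * s_e^2``.
    """
    if not 0 < target_ccc < 1:
        raise ValueError("target_ccc must be in (0, 1)")
    sv2 = volume_log_sd**2

    def gap(se: float) -> float:
        num = math.exp(sv2 + error_corr * se**2) - 1
        den = math.exp(sv2 + se**2) - 1
        return num / den - target_ccc

    if error_corr == 0.0:
        se2 = math.log(1 + (math.exp(sv2) - 1) / target_ccc) - sv2
        return math.sqrt(se2)
    return brentq(gap, 1e-9, 10.0)


def make_paired_cohort(
    n: int = 299,
    seed: int = 0,
    core_log_mean: float = 2.5,
    core_log_sd: float = 1.1,
    penumbra_log_mean: float = 3.3,
    penumbra_log_sd: float = 0.9,
    error_log_sd: float | dict[str, float] = 0.30,
    error_corr: float = 0.0,
    platforms: tuple[str, str] = ("rapid", "jlk"),
) -> pd.DataFrame:
    """Paired per-patient volumes from two noisy platforms plus profiles.

    True core and penumbra volumes are log-normal (positive, right-skewed,
    as stroke lesion volumes are); the hypoperfused volume is their sum.
    Each platform observes every true volume times its own log-normal
    error.  ``error_log_sd`` may be a single value or per-measure
    (``{"core_ml": ..., "hypoperfused_ml": ...}``); use
    :func:`calibrate_error_sd` to target a concordance level.  Deterministic
    under ``seed``.
    """
    if n < 10:
        raise ValueError(f"cohort size must be >= 10, got {n}")
    rng = np.random.default_rng(seed)
    if not isinstance(error_log_sd, dict):
        error_log_sd = {"core_ml": float(error_log_sd), "hypoperfused_ml": float(error_log_sd)}

    true_core = np.exp(rng.normal(core_log_mean, core_log_sd, n))
    true_pen = np.exp(rng.normal(penumbra_log_mean, penumbra_log_sd, n))
    true_hypo = true_core + true_pen

    cov = np.array([[1.0, error_corr], [error_corr, 1.0]])
    chol = np.linalg.cholesky(cov)

    data: dict[str, np.ndarray] = {"id": np.array([f"p{i:04d}" for i in range(n)])}
    ages = np.clip(np.rint(rng.normal(70.9, 11.6, n)), 20, 100).astype(int)
    nihss = np.clip(np.rint(rng.normal(11.5, 7.0, n)), 0, 42).astype(int)
    sites = rng.choice(
        [OcclusionSite.ANTERIOR_LVO.value, OcclusionSite.BASILAR.value, OcclusionSite.NONE.value],
        size=n,
        p=[0.70, 0.10, 0.20],
    )
    data.update(age_years=ages, nihss=nihss, occlusion_site=sites)

    for measure, true_vals in (("core_ml", true_core), ("hypoperfused_ml", true_hypo)):
        se = error_log_sd[measure]
        z = rng.standard_normal((n, 2)) @ chol.T
        for pi, platform in enumerate(platforms):
            data[f"{platform}_{measure}"] = true_vals * np.exp(se * z[:, pi])
    df = pd.DataFrame(data)
    for platform in platforms:
        core_col = df[f"{platform}_core_ml"]
        hypo_col = df[f"{platform}_hypoperfused_ml"]
        df[f"{platform}_mismatch_ml"] = np.clip(hypo_col - core_col, 0.0, None)
        with np.errstate(divide="ignore"):
            df[f"{platform}_mismatch_ratio"] = np.where(core_col > 0, hypo_col / core_col, np.inf)
    df["true_core_ml"] = true_core
    df["true_hypoperfused_ml"] = true_hypo
    return df


def _dawn_profile(rng: np.random.Generator, stratum: str) -> tuple[int, int]:
    if stratum == "A":
        return int(rng.integers(81, 96)), int(rng.integers(10, 31))
    if stratum == "B":
        return int(rng.integers(40, 81)), int(rng.integers(10, 20))
    if stratum == "C":
        return int(rng.integers(40, 81)), int(rng.integers(20, 31))
    raise ValueError(f"unknown DAWN stratum {stratum!r}")


def make_eligibility_cohort(
    trial: str,
    cells: Sequence[int],
    stratum: str | None = None,
    seed: int = 0,
    id_prefix: str = "p",
) -> pd.DataFrame:
    """A cohort realizing an exact eligibility contingency table.

    ``cells`` is (not/not, not/eligible, eligible/not, eligible/eligible)
    with rows = platform 1 ("rapid") and columns = platform 2 ("jlk").  For
    DAWN, ``stratum`` picks the age/NIHSS band ("A": >80 & NIHSS>=10,
    "B": <=80 & 10-19, "C": <=80 & >=20); volumes are drawn on the correct
    side of that stratum's core cutoff.  For DEFUSE-3, ineligible verdicts
    alternate between the three failure modes (large core, small mismatch
    volume, low mismatch ratio).  All patients pass the population gate.
    """
    from .eligibility import DAWN_CORE_CUTOFFS_ML  # local import to avoid cycle

    cells = [int(c) for c in cells]
    if len(cells) != 4 or any(c < 0 for c in cells):
        raise ValueError("cells must be four non-negative counts")
    trial = trial.upper().replace("-", "").replace("_", "")
    rng = np.random.default_rng(seed)
    rows = []
    verdict_pairs = (
        [(False, False)] * cells[0]
        + [(False, True)] * cells[1]
        + [(True, False)] * cells[2]
        + [(True, True)] * cells[3]
    )

    if trial == "DAWN":
        stratum = stratum or "B"
        cutoff = DAWN_CORE_CUTOFFS_ML[{"A": 0, "B": 1, "C": 2}[stratum]]

        def draw(eligible: bool) -> dict:
            core = (
                rng.uniform(2.0, 0.85 * cutoff) if eligible else rng.uniform(1.15 * cutoff, cutoff + 70)
            )
            hypo = core + rng.uniform(20.0, 90.0)
            return {"core_ml": core, "hypoperfused_ml": hypo}

        def profile() -> tuple[int, int]:
            return _dawn_profile(rng, stratum)

    elif trial == "DEFUSE3":

        def draw(eligible: bool) -> dict:
            if eligible:
                core = rng.uniform(2.0, 45.0)
                hypo = core * rng.uniform(2.2, 4.0) + rng.uniform(20.0, 40.0)
            else:
                mode = rng.integers(0, 3)
                if mode == 0:  # core too large
                    core = rng.uniform(78.0, 160.0)
                    hypo = core + rng.uniform(20.0, 60.0)
                elif mode == 1:  # mismatch volume < 15 mL
                    core = rng.uniform(4.0, 40.0)
                    hypo = core + rng.uniform(0.0, 12.0)
                else:  # ratio < 1.8 (large core, modest mismatch)
                    core = rng.uniform(30.0, 60.0)
                    hypo = core * rng.uniform(1.05, 1.55)
            return {"core_ml": core, "hypoperfused_ml": hypo}

        def profile() -> tuple[int, int]:
            return int(rng.integers(45, 86)), int(rng.integers(6, 26))

    else:
        raise ValueError(f"unknown trial {trial!r}")

    for i, (elig_a, elig_b) in enumerate(verdict_pairs):
        age, nihss = profile()
        row = {
            "id": f"{id_prefix}{i:04d}",
            "age_years": age,
            "nihss": nihss,
            "occlusion_site": OcclusionSite.ANTERIOR_LVO.value,
        }
        va, vb = draw(elig_a), draw(elig_b)
        for name, v in (("rapid", va), ("jlk", vb)):
            row[f"{name}_core_ml"] = v["core_ml"]
            row[f"{name}_hypoperfused_ml"] = v["hypoperfused_ml"]
            row[f"{name}_mismatch_ml"] = max(v["hypoperfused_ml"] - v["core_ml"], 0.0)
            row[f"{name}_mismatch_ratio"] = (
                v["hypoperfused_ml"] / v["core_ml"] if v["core_ml"] > 0 else math.inf
            )
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> dict[str, PatientProfile]:
    """Extract PatientProfile objects from a cohort DataFrame."""
    return {
        str(r.id): PatientProfile(int(r.age_years), int(r.nihss), OcclusionSite(r.occlusion_site))
        for r in df.itertuples()
    }
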
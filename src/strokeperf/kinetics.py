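"""MR signal to contrast concentration, and automatic AIF/VOF selection.

Concentration is the standard DSC relation C(t) = -(1/TE) ln(S(t)/S0) with
the proportionality constant between Delta-R2* and gadolinium concentration
set to 1, i.e. concentration is in relative units.  S0 is the mean signal
over the pre-bolus baseline window.

The arterial input function is picked automatically: candidate brain-voxel
curves are scored by peak height divided by (FWHM in frames x arrival
rank), which favours the early, tall, narrow curves characteristic of
feeding arteries; the top-N curves are averaged and a gamma-variate is
fitted to suppress noise and recirculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .io import PerfusionStudy
from .preprocess import BrainMask


@dataclass
class ConcentrationSeries:
    """4-D contrast concentration plus the baseline bookkeeping."""

    conc: np.ndarray
    t0_index: int
    baseline_window: tuple[int, int]  # [start, stop) frame range used for S0
    tr_s: float
    te_s: float

    def __post_init__(self) -> None:
        if self.conc.ndim != 4:
            raise ValueError("concentration series must be 4D")
        if not self.baseline_window[1] <= self.t0_index:
            raise ValueError("baseline frames must precede the bolus-arrival frame")

    @property
    def n_time(self) -> int:
        return self.conc.shape[3]


@dataclass
class GammaVariateFit:
    """Parameters of A * (t - t0)^alpha * exp(-(t - t0)/beta) for t > t0."""

    amplitude: float
    onset_s: float
    alpha: float
    beta_s: float
    converged: bool = True

    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        return gamma_variate(np.asarray(t_s, dtype=float), self.amplitude, self.onset_s, self.alpha, self.beta_s)


@dataclass
class InputFunction:
    """A selected arterial input (or venous output) curve."""

    curve: np.ndarray
    voxel_ids: np.ndarray
    role: str  # "AIF" or "VOF"
    tr_s: float
    fit_params: Optional[GammaVariateFit] = None
    fitted_curve: Optional[np.ndarray] = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=np.float64)
        if self.curve.max(initial=0.0) <= 0:
            raise ValueError("input function peak must be positive")

    @property
    def effective_curve(self) -> np.ndarray:
        """Gamma-variate-filtered curve when the fit converged, else the raw mean."""
        if self.fit_params is not None and self.fit_params.converged:
            return self.fitted_curve
        return self.curve


def gamma_variate(t_s: np.ndarray, amplitude: float, onset_s: float, alpha: float, beta_s: float) -> np.ndarray:
    """Gamma-variate bolus model; zero at and before onset."""
    dt = np.clip(t_s - onset_s, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = amplitude * dt**alpha * np.exp(-dt / beta_s)
    return np.where(t_s > onset_s, out, 0.0)


def detect_bolus_arrival(
    mean_curve: np.ndarray,
    k_sd: float = 2.0,
    baseline_frames: int = 8,
    smooth: int = 3,
) -> int:
    """First frame where the smoothed whole-brain mean signal drops below baseline.

    A trailing ``smooth``-frame moving average is compared against
    baseline_mean - k_sd * baseline_sd, where the baseline statistics come
    from the first ``baseline_frames`` frames.  Returns an index >= 3 so a
    usable S0 window exists.
    """
    curve = np.asarray(mean_curve, dtype=np.float64)
    if curve.size < 20:
        raise ValueError(f"bolus detection needs >= 20 frames, got {curve.size}")
    base = curve[:baseline_frames]
    mean, sd = float(base.mean()), float(base.std())
    kernel = np.ones(smooth) / smooth
    # trailing (causal) moving average so the detected frame is not pulled early
    smoothed = np.convolve(curve, kernel)[: curve.size]
    smoothed[: smooth - 1] = curve[: smooth - 1]
    # relative epsilon so an exactly-flat (noiseless) baseline never triggers
    # on floating-point rounding of the moving average
    eps = 1e-9 * max(abs(mean), 1.0)
    below = np.flatnonzero(smoothed < mean - k_sd * sd - eps)
    if below.size == 0:
        raise ValueError("no bolus detected: signal never drops below baseline")
    t0 = int(below[0])
    if t0 < 3:
        raise ValueError(f"bolus arrives at frame {t0}: insufficient pre-bolus baseline")
    return t0


def signal_to_concentration(
    study: PerfusionStudy,
    brain: BrainMask,
    t0_index: int,
    max_bad_fraction: float = 0.1,
) -> ConcentrationSeries:
    """Convert MR signal to concentration inside the brain mask.

    Voxels with non-positive baseline signal are zeroed and counted; more
    than ``max_bad_fraction`` of the brain being unusable is an error (it
    indicates a masking or acquisition problem, not a few noise voxels).
    """
    s0 = study.signal[..., :t0_index].mean(axis=3)
    # voxels with near-zero baseline (mask edge / air leakage) have no usable
    # signal and would otherwise produce huge spurious concentration spikes
    s0_floor = 0.05 * np.median(s0[brain.mask]) if brain.n_voxels else 0.0
    bad = (s0 <= max(s0_floor, 0.0)) & brain.mask
    n_bad = int(bad.sum())
    if n_bad > max_bad_fraction * max(brain.n_voxels, 1):
        raise ValueError(
            f"{n_bad} of {brain.n_voxels} brain voxels have non-positive baseline signal"
        )
    conc = np.zeros_like(study.signal)
    ok = brain.mask & ~bad
    s0_ok = s0[ok]
    sig = study.signal[ok]  # (nvox, t)
    floor = np.maximum(s0_ok[:, None] * 1e-6, 1e-12)
    ratio = np.maximum(sig, floor) / s0_ok[:, None]
    conc[ok] = -np.log(ratio) / study.te_s
    return ConcentrationSeries(
        conc=conc,
        t0_index=t0_index,
        baseline_window=(0, t0_index),
        tr_s=study.tr_s,
        te_s=study.te_s,
    )


def _curve_features(curves: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak height, FWHM (frames, interpolated), and arrival (frames, interpolated).

    Arrival is the first crossing of half peak; width is the distance to the
    first post-peak drop below half peak (right-censored at the series end).
    """
    n_vox, n_t = curves.shape
    peak = curves.max(axis=1)
    pidx = curves.argmax(axis=1)
    half = peak / 2.0
    above = curves >= half[:, None]

    up = above.argmax(axis=1)  # first frame at/above half peak
    prev = np.clip(up - 1, 0, None)
    c_prev = curves[np.arange(n_vox), prev]
    c_up = curves[np.arange(n_vox), up]
    denom = np.where(c_up > c_prev, c_up - c_prev, 1.0)
    frac = np.clip((half - c_prev) / denom, 0.0, 1.0)
    arrival = np.where(up > 0, up - 1 + frac, 0.0)

    after_peak = np.arange(n_t)[None, :] > pidx[:, None]
    below_after = (~above) & after_peak
    has_down = below_after.any(axis=1)
    down = np.where(has_down, below_after.argmax(axis=1), n_t - 1)
    dprev = np.clip(down - 1, 0, None)
    c_dprev = curves[np.arange(n_vox), dprev]
    c_down = curves[np.arange(n_vox), down]
    ddenom = np.where(c_dprev > c_down, c_dprev - c_down, 1.0)
    dfrac = np.clip((c_dprev - half) / ddenom, 0.0, 1.0)
    down_x = np.where(has_down, down - 1 + dfrac, float(n_t - 1))

    fwhm = np.maximum(down_x - arrival, 0.5)
    return peak, fwhm, arrival


def _select_input(
    conc: ConcentrationSeries,
    brain: BrainMask,
    n_select: int,
    role: str,
) -> InputFunction:
    flat_ids = np.flatnonzero(brain.mask.ravel())
    curves = conc.conc.reshape(-1, conc.n_time)[flat_ids]
    positive = curves.max(axis=1) > 0
    flat_ids, curves = flat_ids[positive], curves[positive]
    if flat_ids.size < n_select:
        raise ValueError(
            f"only {flat_ids.size} candidate voxels with positive peak; need >= {n_select}"
        )
    peak, fwhm, arrival = _curve_features(curves)
    if role == "AIF":
        rank = rankdata(arrival, method="ordinal")
        score = peak / (fwhm * rank)
    else:  # VOF: largest area, latest arrival
        area = np.trapezoid(curves, dx=conc.tr_s, axis=1)
        rank = rankdata(arrival, method="ordinal")
        score = area * rank
    order = np.lexsort((flat_ids, -score))[:n_select]
    chosen = flat_ids[order]
    mean_curve = curves[order].mean(axis=0)
    fit = fitted = None
    try:
        fit, fitted = fit_gamma_variate(mean_curve, conc.tr_s)
    except (ValueError, RuntimeError):
        warnings.warn(f"{role} gamma-variate fit failed; using raw mean curve", stacklevel=2)
    return InputFunction(
        curve=mean_curve,
        voxel_ids=chosen,
        role=role,
        tr_s=conc.tr_s,
        fit_params=fit,
        fitted_curve=fitted,
        scores={"peak": peak[order], "fwhm_frames": fwhm[order], "arrival_frames": arrival[order]},
    )


def select_aif(conc: ConcentrationSeries, brain: BrainMask, n_select: int = 10) -> InputFunction:
    """Automatically select the arterial input function (top-N scored voxels)."""
    return _select_input(conc, brain, n_select, "AIF")


def select_vof(conc: ConcentrationSeries, brain: BrainMask, n_select: int = 10) -> InputFunction:
    """Select the venous output function (largest-area, late-arriving curves).

    Used for reporting/QC only; no partial-volume rescaling of the AIF is
    performed.
    """
    return _select_input(conc, brain, n_select, "VOF")


def fit_gamma_variate(curve: np.ndarray, tr_s: float) -> tuple[GammaVariateFit, np.ndarray]:
    """Least-squares gamma-variate fit of a first-pass bolus curve.

    The fit is restricted to frames up to the first post-peak local minimum
    (recirculation cutoff).  A fit whose peak deviates more than 20% from
    the observed peak is marked non-converged; callers then fall back to the
    raw curve.
    """
    curve = np.asarray(curve, dtype=np.float64)
    peak = curve.max(initial=0.0)
    if peak <= 0:
        raise ValueError("no peak: curve has no positive values")
    pidx = int(curve.argmax())
    # recirculation cutoff: first local minimum after the global peak
    cutoff = curve.size
    for i in range(pidx + 1, curve.size - 1):
        if curve[i] <= curve[i - 1] and curve[i] < curve[i + 1]:
            cutoff = i + 1
            break
    t = np.arange(curve.size) * tr_s
    t_fit, c_fit = t[:cutoff], curve[:cutoff]

    rise = np.flatnonzero(curve[: pidx + 1] > 0.05 * peak)
    t0_guess = t[rise[0]] - tr_s / 2 if rise.size else 0.0
    t0_guess = float(np.clip(t0_guess, 0.0, max(t[pidx] - tr_s, 0.0)))
    alpha0 = 3.0
    beta0 = max((t[pidx] - t0_guess) / alpha0, tr_s / 2)
    amp0 = peak / max((alpha0 * beta0) ** alpha0 * np.exp(-alpha0), 1e-12)

    bounds = ([0.0, 0.0, 0.3, tr_s / 10], [np.inf, max(t[pidx], tr_s), 25.0, 60.0])
    p0 = [amp0, t0_guess, alpha0, beta0]
    try:
        popt, _ = curve_fit(gamma_variate, t_fit, c_fit, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    fit = GammaVariateFit(*[float(p) for p in popt], converged=converged)
    fitted = fit(t)
    if converged and abs(fitted.max() - peak) > 0.2 * peak:
        fit.converged = False
    return fit, fitted
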
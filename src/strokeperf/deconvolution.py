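"""Block-circulant SVD deconvolution and perfusion-map computation.

Tissue concentration obeys c(t) = CBF * (AIF conv R)(t) with R the residue
function.  Discretized, c = D k with D the (time-shift invariant) circulant
matrix built from the zero-padded AIF and k(t) = CBF * R(t - delay).  The
circulant embedding makes the estimate insensitive to tracer arrival delay:
a delayed tissue curve simply shifts k, so CBF (the maximum of k) is
preserved and Tmax (the argmax) tracks the delay.  Regularization is
truncation of singular values below a fixed fraction of the largest
(cSVD).  Zero padding is exactly 2x the time dimension.

Truncated cSVD is known to underestimate CBF when MTT is short relative to
TR (the sharp residue edge lives in the truncated part of the spectrum);
rank order across tissues is nevertheless preserved, which is what the
downstream Tmax/volumetric thresholds rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import circulant, svd

from .kinetics import ConcentrationSeries, InputFunction
from .preprocess import BrainMask


@dataclass
class PerfusionMaps:
    """Voxelwise CBF (relative), CBV (relative), MTT (s), and Tmax (s) maps."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt_s: np.ndarray
    tmax_s: np.ndarray
    voxel_mm: tuple[float, float, float]
    tr_s: float
    diagnostics: dict = field(default_factory=dict)


def build_circulant(aif_curve: np.ndarray, n_pad: int, tr_s: float = 1.0) -> np.ndarray:
    """Circulant convolution matrix D[i, j] = TR * a[(i - j) mod L].

    ``aif_curve`` is zero-padded to length ``n_pad`` (must be >= the curve
    length); the circulant structure D[i, j] = D[(i+1) mod L, (j+1) mod L]
    holds exactly by construction.
    """
    a = np.asarray(aif_curve, dtype=np.float64)
    if a.ndim != 1:
        raise ValueError("AIF curve must be 1-D")
    if not np.isfinite(a).all():
        raise ValueError("AIF curve contains non-finite values")
    if n_pad < a.size:
        raise ValueError(f"n_pad ({n_pad}) must be >= curve length ({a.size})")
    padded = np.zeros(n_pad)
    padded[: a.size] = a
    return tr_s * circulant(padded)


def _truncated_pinv(d: np.ndarray, threshold_frac: float) -> np.ndarray:
    u, s, vt = svd(d)
    keep = s >= threshold_frac * s[0]
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (vt.T * s_inv) @ u.T


def deconvolve_csvd(
    conc: ConcentrationSeries,
    aif: InputFunction,
    threshold_frac: float = 0.1,
    brain: BrainMask | None = None,
) -> np.ndarray:
    """Deconvolve tissue concentration by the AIF; returns k(t) = CBF * R(t).

    The returned field has 2 * n_time frames (circulant padding); delayed
    tissue appears at the lag matching its delay.  Singular values below
    ``threshold_frac`` of the largest are zeroed.  The gamma-variate-fitted
    AIF is used when the fit converged.
    """
    if not 0.0 < threshold_frac < 0.5:
        raise ValueError(f"threshold_frac must be in (0, 0.5), got {threshold_frac}")
    curve = np.asarray(aif.effective_curve, dtype=np.float64)
    if curve.size != conc.n_time:
        raise ValueError("AIF and concentration series are on different time grids")
    if not np.any(curve):
        raise ValueError("all-zero AIF")
    n = conc.n_time
    length = 2 * n
    d = build_circulant(curve, length, conc.tr_s)
    d_pinv = _truncated_pinv(d, threshold_frac)

    shape3 = conc.conc.shape[:3]
    if brain is not None:
        flat = np.flatnonzero(brain.mask.ravel())
    else:
        flat = np.arange(int(np.prod(shape3)))
    c_mat = np.zeros((length, flat.size))
    c_mat[:n] = conc.conc.reshape(-1, n)[flat].T
    k_mat = d_pinv @ c_mat

    k_field = np.zeros((*shape3, length))
    k_field.reshape(-1, length)[flat] = k_mat.T
    return k_field


def compute_maps(
    k_field: np.ndarray,
    conc: ConcentrationSeries,
    aif: InputFunction,
    brain: BrainMask,
    voxel_mm: tuple[float, float, float],
    eps_frac: float = 1e-6,
) -> PerfusionMaps:
    """Summarize the residue field into CBF, CBV, MTT, and Tmax maps.

    CBF is max_t k(t); Tmax is TR * argmax_t k(t) on the TR grid (first
    maximum on ties, no sub-frame interpolation); CBV is the ratio of
    trapezoidal areas under the tissue and arterial curves; MTT = CBV/CBF
    where CBF exceeds a small fraction of the in-brain maximum, else 0.
    Lags in the wrap-around (second) half of the circulant axis represent
    negative delays and are clamped to Tmax = 0.
    """
    n = conc.n_time
    tr = conc.tr_s
    mask = brain.mask

    k_clean = np.nan_to_num(k_field, nan=0.0, posinf=0.0, neginf=0.0)
    n_nan = int((~np.isfinite(k_field)).sum())

    cbf = k_clean.max(axis=3)
    idx = k_clean.argmax(axis=3)
    wrapped = idx >= n
    tmax = np.where(wrapped, 0.0, idx * tr)

    aif_area = np.trapezoid(np.asarray(aif.effective_curve, dtype=np.float64), dx=tr)
    conc_clean = np.nan_to_num(conc.conc, nan=0.0, posinf=0.0, neginf=0.0)
    n_nan += int((~np.isfinite(conc.conc)).sum())
    cbv = np.trapezoid(conc_clean, dx=tr, axis=3) / aif_area

    cbf = np.where(mask, np.clip(cbf, 0.0, None), 0.0)
    cbv = np.where(mask, np.clip(cbv, 0.0, None), 0.0)
    tmax = np.where(mask, tmax, 0.0)

    eps = eps_frac * max(cbf.max(initial=0.0), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > eps, cbv / np.where(cbf > eps, cbf, 1.0), 0.0)

    return PerfusionMaps(
        cbf=cbf,
        cbv=cbv,
        mtt_s=mtt,
        tmax_s=tmax,
        voxel_mm=tuple(voxel_mm),
        tr_s=tr,
        diagnostics={"n_nonfinite_zeroed": n_nan, "n_wrapped_tmax": int((wrapped & mask).sum())},
    )
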
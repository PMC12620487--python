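"""Method-agreement statistics for paired perfusion platforms.

Implements Lin's concordance correlation coefficient (moment estimators
with 1/n normalization, Fisher-z confidence interval), Pearson correlation,
Bland-Altman bias and 95% limits of agreement, Cohen's kappa for 2x2
eligibility tables (Fleiss-Cohen-Everitt asymptotic SE, CI truncated to
[-1, 1]), and the qualitative magnitude scale
poor/fair/moderate/substantial/excellent.

The model-style entry point is :class:`PlatformAgreement`: construct from a
tidy per-patient DataFrame with one column per platform/measure, call
``fit()``, and read the per-measure :class:`AgreementReport` objects (or
``summary()``) off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAGNITUDE_BANDS = (
    (0.00, 0.20, "poor"),
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
    (0.81, 1.00, "excellent"),
)


@dataclass
class ContingencyTable:
    """2x2 eligibility cross-table; rows = platform 1, columns = platform 2."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {self.cells.shape}")
        if (self.cells < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.cells.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.cells.T)

    def as_dict(self) -> dict:
        (a, b), (c, d) = self.cells.tolist()
        return {"not_not": a, "not_eligible": b, "eligible_not": c, "eligible_eligible": d, "n": self.n}


@dataclass
class EstimateCI:
    estimate: float
    ci_low: float
    ci_high: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.estimate, self.ci_low, self.ci_high)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    percent_agreement: float


@dataclass
class AgreementReport:
    """All agreement statistics for one paired measure.

    ``ba_bias`` is mean(platform1 - platform2); the platform order is
    carried in ``platforms`` so the sign convention is always explicit.
    """

    measure: str
    platforms: tuple[str, str]
    n: int
    ccc: EstimateCI
    pearson_r: float
    ba_bias: float
    ba_loa: tuple[float, float]
    magnitude: str
    kappa: KappaResult | None = None

    def as_dict(self) -> dict:
        out = {
            "measure": self.measure,
            "platforms": list(self.platforms),
            "n": self.n,
            "ccc": self.ccc.estimate,
            "ccc_ci": [self.ccc.ci_low, self.ccc.ci_high],
            "pearson_r": self.pearson_r,
            "ba_bias": self.ba_bias,
            "ba_loa": list(self.ba_loa),
            "magnitude": self.magnitude,
        }
        if self.kappa is not None:
            out["kappa"] = self.kappa.kappa
            out["kappa_ci"] = [self.kappa.ci_low, self.kappa.ci_high]
            out["percent_agreement"] = self.kappa.percent_agreement
        return out


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def ccc(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> EstimateCI:
    """Lin's concordance correlation coefficient with Fisher-z CI.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with biased
    (1/n) moment estimators, so perfect agreement gives exactly 1.  The CI
    uses the z-transform with Lin's (1989) asymptotic standard error.
    """
    x, y = _paired(x, y, 3)
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both inputs constant with equal means")
    est = 2 * sxy / denom

    if sx2 == 0 or sy2 == 0:
        return EstimateCI(est, est, est)
    r = sxy / math.sqrt(sx2 * sy2)
    if abs(est) >= 1.0 or r == 0:
        return EstimateCI(est, est, est)
    u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)
    one = 1 - est**2
    var_z = (
        (1 - r**2) * est**2 / (one * r**2)
        + 2 * est**3 * (1 - est) * u2 / (r * one**2)
        - est**4 * u2**2 / (2 * r**2 * one**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    z = np.arctanh(est)
    lo, hi = np.tanh(z - zcrit * math.sqrt(var_z)), np.tanh(z + zcrit * math.sqrt(var_z))
    return EstimateCI(float(est), float(lo), float(hi))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation."""
    x, y = _paired(x, y, 3)
    if (x == x[0]).all() or (y == y[0]).all():
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bias = mean(x - y) and 95% limits of agreement bias +- 1.96 SD(x - y).

    SD uses the n-1 (sample) denominator.  Returns (bias, (lower, upper),
    per-pair differences).
    """
    x, y = _paired(x, y, 2)
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd), diffs


def cohens_kappa(table: ContingencyTable, alpha: float = 0.05) -> KappaResult:
    """Chance-corrected agreement for a 2x2 table.

    kappa = (po - pe)/(1 - pe); the asymptotic SE is Fleiss, Cohen and
    Everitt's large-sample formula, and the CI is truncated to [-1, 1].
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table: kappa undefined")
    p = table.cells / n
    po = float(np.trace(p))
    pr, pc = p.sum(axis=1), p.sum(axis=0)
    pe = float(pr @ pc)
    if pe == 1.0:
        raise ValueError("kappa undefined: degenerate marginals (pe = 1)")
    kappa = (po - pe) / (1 - pe)

    a_term = sum(p[i, i] * (1 - (pr[i] + pc[i]) * (1 - kappa)) ** 2 for i in range(2))
    b_term = (1 - kappa) ** 2 * sum(
        p[i, j] * (pc[j] + pr[i]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c_term = (kappa - pe * (1 - kappa)) ** 2
    var = max(a_term + b_term - c_term, 0.0) / (n * (1 - pe) ** 2)
    se = math.sqrt(var)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo = max(kappa - zcrit * se, -1.0)
    hi = min(kappa + zcrit * se, 1.0)
    return KappaResult(float(kappa), float(lo), float(hi), float(se), 100.0 * po)


def magnitude_label(value: float) -> str:
    """Qualitative agreement band for a coefficient in [-1, 1].

    Values are rounded to 2 decimals before bucketing (the printed band
    edges leave e.g. (0.20, 0.21) unassigned); negative values are 'poor'.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"agreement coefficient must be in [-1, 1], got {value}")
    v = round(value, 2)
    if v < 0:
        return "poor"
    for lo, hi, label in MAGNITUDE_BANDS:
        if lo <= v <= hi:
            return label
    return "poor"  # pragma: no cover


def compute_agreement(
    x: Sequence[float],
    y: Sequence[float],
    measure: str = "volume_ml",
    platforms: tuple[str, str] = ("platform1", "platform2"),
    table: ContingencyTable | None = None,
) -> AgreementReport:
    """Assemble the full agreement report for one paired measure."""
    x, y = _paired(x, y, 3)
    c = ccc(x, y)
    r = pearson(x, y)
    bias, loa, _ = bland_altman(x, y)
    kap = cohens_kappa(table) if table is not None else None
    return AgreementReport(
        measure=measure,
        platforms=platforms,
        n=x.size,
        ccc=c,
        pearson_r=r,
        ba_bias=bias,
        ba_loa=loa,
        magnitude=magnitude_label(c.estimate),
        kappa=kap,
    )


class PlatformAgreement:
    """Agreement model for two platforms measuring the same volumes.

    Parameters
    ----------
    data : DataFrame
        Tidy per-patient table with columns ``{platform}_{measure}`` for
        each platform/measure combination.
    measures : sequence of str
        Measure names, e.g. ``("core_ml", "hypoperfused_ml", "mismatch_ml")``.
    platforms : (str, str)
        Column prefixes; the first platform defines the sign of the
        Bland-Altman bias.

    Examples
    --------
    >>> model = PlatformAgreement(df, measures=("core_ml",), platforms=("rapid", "jlk"))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: pd.DataFrame,
        measures: Sequence[str] = ("core_ml", "hypoperfused_ml", "mismatch_ml"),
        platforms: tuple[str, str] = ("rapid", "jlk"),
    ) -> None:
        self.data = data
        self.measures = tuple(measures)
        self.platforms = platforms
        for m in self.measures:
            for p in platforms:
                if f"{p}_{m}" not in data.columns:
                    raise ValueError(f"missing column '{p}_{m}'")

    def fit(self) -> "AgreementResults":
        reports = {}
        for m in self.measures:
            x = self.data[f"{self.platforms[0]}_{m}"].to_numpy(dtype=float)
            y = self.data[f"{self.platforms[1]}_{m}"].to_numpy(dtype=float)
            reports[m] = compute_agreement(x, y, measure=m, platforms=self.platforms)
        return AgreementResults(self, reports)


class AgreementResults:
    """Fitted agreement statistics; one :class:`AgreementReport` per measure."""

    def __init__(self, model: PlatformAgreement, reports: dict[str, AgreementReport]) -> None:
        self.model = model
        self.reports = reports

    def report(self, measure: str) -> AgreementReport:
        return self.reports[measure]

    def summary(self) -> str:
        p1, p2 = self.model.platforms
        lines = [
            "Platform agreement summary",
            f"  platforms: {p1} vs {p2} (bias = {p1} - {p2})",
            f"  n = {len(self.model.data)}",
            "",
            f"{'measure':<18}{'CCC (95% CI)':<26}{'Pearson r':<12}{'bias':>9}{'LoA':>22}  magnitude",
        ]
        for m, rep in self.reports.items():
            ci = f"{rep.ccc.estimate:.3f} ({rep.ccc.ci_low:.3f}, {rep.ccc.ci_high:.3f})"
            loa = f"({rep.ba_loa[0]:.2f}, {rep.ba_loa[1]:.2f})"
            lines.append(
                f"{m:<18}{ci:<26}{rep.pearson_r:<12.3f}{rep.ba_bias:>9.2f}{loa:>22}  {rep.magnitude}"
            )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {m: rep.as_dict() for m, rep in self.reports.items()}

    def plot_bland_altman(self, measure: str, ax=None):
        """Bland-Altman plot (difference vs mean with bias and LoA lines)."""
        import matplotlib.pyplot as plt

        rep = self.reports[measure]
        p1, p2 = self.model.platforms
        x = self.model.data[f"{p1}_{measure}"].to_numpy(dtype=float)
        y = self.model.data[f"{p2}_{measure}"].to_numpy(dtype=float)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter((x + y) / 2, x - y, s=12, alpha=0.6)
        ax.axhline(rep.ba_bias, color="k", lw=1)
        for lim in rep.ba_loa:
            ax.axhline(lim, color="k", lw=1, ls="--")
        ax.set_xlabel(f"mean of {p1} and {p2} ({measure})")
        ax.set_ylabel(f"{p1} - {p2}")
        ax.set_title(f"Bland-Altman: {measure}")
        return ax
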
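"""Radiocarbon chronology and diet-based reservoir correction.

Calibration maps a conventional radiocarbon age m ± sigma onto the calendar
scale through a calibration curve (cal BP grid, curve 14C age mu, curve
sigma): posterior(theta) ∝ exp(-(m - mu(theta))^2 / (2 (sigma^2 +
sigma_curve(theta)^2))), normalized on the grid, summarized by 95.4% highest
posterior density (HPD) intervals — the 2-sigma convention of calibration
software. Replicate measurements of one sample are pooled by Ward-Wilson
inverse-variance combination with a chi-square concordance test. Collagen
delta13C places a diet on a linear terrestrial/marine mixing line whose
marine fraction scales the marine reservoir offset subtracted before
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RadiocarbonDate:
    uncal_bp: float
    sigma: float
    lab_id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("radiocarbon sigma must be positive")


@dataclass
class CalCurve:
    """Calibration curve on a strictly increasing cal BP grid."""

    cal_bp: np.ndarray
    mu_c14: np.ndarray
    sigma_curve: np.ndarray
    name: str = "synthetic"

    def __post_init__(self):
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.mu_c14 = np.asarray(self.mu_c14, dtype=float)
        self.sigma_curve = np.asarray(self.sigma_curve, dtype=float)
        if not np.all(np.diff(self.cal_bp) > 0):
            raise ValueError("cal BP grid must be strictly increasing")
        if np.any(self.sigma_curve < 0):
            raise ValueError("curve sigma must be non-negative")

    def interp(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = np.interp(theta, self.cal_bp, self.mu_c14)
        sd = np.interp(theta, self.cal_bp, self.sigma_curve)
        return mu, sd


@dataclass
class CalibratedDate:
    date: RadiocarbonDate
    grid_cal_bp: np.ndarray
    density: np.ndarray
    hpd_954: list          # [(old_cal_bp, young_cal_bp, mass)], older first
    reservoir_corrected: bool = False

    @property
    def median_cal_bp(self) -> float:
        cdf = np.cumsum(self.density)
        return float(np.interp(0.5, cdf, self.grid_cal_bp))

    def hpd_cal_bce(self) -> list:
        """HPD intervals as (older BCE, younger BCE) pairs, BCE positive."""
        return [(cal_bp_to_bce(a), cal_bp_to_bce(b), m) for a, b, m in self.hpd_954]


@dataclass
class DietModel:
    """Two-endpoint protein-source mixing model for collagen delta13C.

    Defaults: a fully terrestrial C3 diet sits at -22 permil, a fully marine
    diet at -10 permil, and a fully marine consumer carries a 273 +/- 18 yr
    reservoir age.
    """

    delta13c_terrestrial: float = -22.0
    delta13c_marine: float = -10.0
    reservoir_full_marine: float = 273.0
    reservoir_sigma: float = 18.0

    def __post_init__(self):
        if self.delta13c_marine <= self.delta13c_terrestrial:
            raise ValueError("marine endpoint must exceed terrestrial endpoint")


def read_calcurve(path, name: Optional[str] = None) -> CalCurve:
    """Read a calibration curve in the standard IntCal distribution layout.

    First three columns are cal BP, 14C age BP and curve sigma; '#' lines are
    comments; commas or whitespace separate fields. Rows are re-sorted to an
    increasing cal BP grid.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    arr = np.asarray(rows)
    arr = arr[np.argsort(arr[:, 0])]
    return CalCurve(arr[:, 0], arr[:, 1], arr[:, 2], name or str(path))


def cal_bp_to_bce(cal_bp: float) -> float:
    """Calendar years BP (datum 1950 CE) to years BCE (positive = BCE)."""
    return cal_bp - 1950.0


def calibrate(d: RadiocarbonDate, curve: CalCurve, grid_step: float = 1.0,
              hpd_mass: float = 0.954,
              reservoir_corrected: bool = False) -> CalibratedDate:
    """Calibrate one radiocarbon date against a curve.

    The posterior is evaluated on a regular cal BP grid spanning the curve
    (linear curve interpolation), normalized to sum to 1, and summarized as
    the smallest set of grid cells holding >= ``hpd_mass``, merged into
    intervals with endpoints rounded outward to whole years.
    """
    lo, hi = float(curve.cal_bp[0]), float(curve.cal_bp[-1])
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    mu, sd = curve.interp(grid)
    var = d.sigma ** 2 + sd ** 2
    logp = -0.5 * (d.uncal_bp - mu) ** 2 / var - 0.5 * np.log(var)
    logp -= logp.max()
    dens = np.exp(logp)
    total = dens.sum()
    if total <= 0:
        raise ValueError("date outside curve span")
    # guard: posterior must not be truncated by the grid edge
    edge = max(dens[0], dens[-1]) / dens.max()
    if edge > 1e-3:
        raise ValueError(
            f"date {d.uncal_bp}±{d.sigma} lies at the edge of curve "
            f"{curve.name!r}; posterior would be truncated")
    dens /= total
    order = np.argsort(dens)[::-1]
    csum = np.cumsum(dens[order])
    k = int(np.searchsorted(csum, hpd_mass) + 1)
    # tie-inclusive: cells equal in density to the last selected cell enter
    # too, so symmetric posteriors yield symmetric intervals
    thresh = dens[order[k - 1]]
    sel = dens >= thresh * (1 - 1e-12)
    intervals = []
    i = 0
    while i < len(grid):
        if sel[i]:
            j = i
            while j + 1 < len(grid) and sel[j + 1]:
                j += 1
            mass = float(dens[i:j + 1].sum())
            # cal BP: older bound is the larger value; round outward
            intervals.append((float(np.ceil(grid[j])), float(np.floor(grid[i])), mass))
            i = j + 1
        else:
            i += 1
    intervals.sort(key=lambda t: -t[0])
    return CalibratedDate(d, grid, dens, intervals, reservoir_corrected)


def combine_dates(ds: Sequence[RadiocarbonDate]) -> tuple[RadiocarbonDate, float, bool]:
    """Ward-Wilson inverse-variance pooling of replicate dates.

    Returns (combined date, chi-square statistic, concordance flag); the flag
    is True when chi2 < chi2_{0.95, n-1}.
    """
    if len(ds) < 2:
        raise ValueError("combine_dates needs at least two dates")
    m = np.array([d.uncal_bp for d in ds])
    s = np.array([d.sigma for d in ds])
    w = 1.0 / s ** 2
    mbar = float(np.sum(w * m) / np.sum(w))
    sbar = float(np.sum(w) ** -0.5)
    chi2 = float(np.sum(((m - mbar) / s) ** 2))
    crit = stats.chi2.ppf(0.95, len(ds) - 1)
    combined = RadiocarbonDate(mbar, sbar,
                               lab_id="combined",
                               sample_id=ds[0].sample_id)
    return combined, chi2, bool(chi2 < crit)


def marine_fraction(delta13c: float, diet: DietModel = DietModel()) -> float:
    """Marine protein fraction by linear two-endpoint mixing, clamped to [0,1]."""
    a = ((delta13c - diet.delta13c_terrestrial)
         / (diet.delta13c_marine - diet.delta13c_terrestrial))
    return float(min(1.0, max(0.0, a)))


def reservoir_correct(d: RadiocarbonDate, alpha: float,
                      diet: DietModel = DietModel()) -> RadiocarbonDate:
    """Subtract the diet-proportional marine reservoir offset.

    m' = m - alpha * R, sigma' = sqrt(sigma^2 + (alpha * sigma_R)^2).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("marine fraction must lie in [0, 1]")
    m = d.uncal_bp - alpha * diet.reservoir_full_marine
    s = float(np.hypot(d.sigma, alpha * diet.reservoir_sigma))
    return RadiocarbonDate(m, s, d.lab_id, d.sample_id)


def format_bce_range(intervals: Sequence[tuple]) -> str:
    """Render HPD intervals as 'older-younger' BCE strings, older first."""
    parts = []
    for a, b, _ in intervals:
        parts.append(f"{cal_bp_to_bce(a):.0f}–{cal_bp_to_bce(b):.0f}")
    return ", ".join(parts)


def plot_intervals(calibrated: Sequence[CalibratedDate], labels: Sequence[str],
                   path=None):
    """Horizontal-bar summary of 95.4% ranges (one row per sample)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(calibrated) + 1))
    for i, (cd, lab) in enumerate(zip(calibrated, labels)):
        for a, b, _ in cd.hpd_954:
            ax.plot([a, b], [i, i], lw=4, color="steelblue")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("cal BP")
    ax.invert_xaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
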
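"""Whole-genome duplication dating from Ks distributions.

A WGD leaves a peak in the distribution of synonymous distances (Ks) between
retained paralog pairs.  The workflow implemented here:

1. filter a batch of NG86 Ks estimates to a usable sample (status ``ok``,
   bounds that remove allelic near-zero pairs and the saturated tail);
2. fit a Gaussian kernel density (Silverman's rule by default) and locate
   its peaks;
3. calibrate a per-year synonymous substitution rate r from an *ortholog*
   Ks peak plus a divergence-time interval (r = Ks / 2T applied at each
   time bound);
4. date the WGD with  T = Ks_peak / (2 r),  propagating the rate interval
   into an age interval reported in million years (MY).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .kaks import STATUS_OK

_YEARS_PER_MY = 1.0e6


@dataclass
class KsSample:
    """Filtered Ks values plus bookkeeping of what was dropped and why."""

    values: np.ndarray
    filter_min: float
    filter_max: float
    dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def filter_ks(table: pd.DataFrame, filter_min: float = 0.01,
              filter_max: float = 5.0) -> KsSample:
    """Keep ``status == ok`` rows with filter_min <= Ks <= filter_max.

    Counts of rows dropped per reason (non-ok status, out of bounds) are
    retained on the returned sample.
    """
    if filter_min >= filter_max:
        raise ValueError(f"filter_min {filter_min} must be < filter_max {filter_max}")
    ks = table["ks"].to_numpy(dtype=float)
    status_ok = (table["status"] == STATUS_OK).to_numpy()
    finite = np.isfinite(ks)
    in_bounds = finite & (ks >= filter_min) & (ks <= filter_max)
    keep = status_ok & in_bounds
    dropped = {
        "not_ok_status": int((~status_ok).sum()),
        "out_of_bounds": int((status_ok & ~in_bounds).sum()),
    }
    return KsSample(values=ks[keep], filter_min=filter_min,
                    filter_max=filter_max, dropped=dropped)


@dataclass
class DensityModel:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("density grid must be strictly increasing")


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = (q75 - q25) / 1.34
    scale = min(x for x in (sd, iqr) if x > 0) if max(sd, iqr) > 0 else 0.0
    if scale <= 0:
        raise ValueError(
            "sample has zero spread; supply an explicit bandwidth"
        )
    return 0.9 * scale * n ** (-0.2)


def fit_density(sample: KsSample, bandwidth: float | str = "silverman",
                grid_points: int = 512) -> DensityModel:
    """Gaussian KDE of the Ks sample on a uniform grid over the filter bounds.

    ``bandwidth`` is either the string ``"silverman"`` or an absolute kernel
    standard deviation.  The density is renormalised to integrate to 1 over
    the grid (trapezoid rule).  Requires at least 50 retained values.
    """
    values = np.asarray(sample.values, dtype=float)
    if len(values) < 50:
        raise ValueError(
            f"need >= 50 Ks values to fit a density, got {len(values)}"
        )
    if grid_points < 512:
        grid_points = 512
    h = _silverman_bandwidth(values) if bandwidth == "silverman" else float(bandwidth)
    if h <= 0:
        raise ValueError(f"bandwidth must be > 0, got {h}")
    grid = np.linspace(sample.filter_min, sample.filter_max, grid_points)
    # vectorised Gaussian KDE; zero-variance-safe (unlike a covariance-based KDE)
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * h * math.sqrt(2 * math.pi))
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density (no mass on the grid)")
    return DensityModel(grid=grid, density=dens / area, bandwidth=h)


@dataclass(frozen=True)
class KsPeak:
    mode: float
    height: float
    prominence: float


def find_density_peaks(model: DensityModel,
                       min_prominence: float | None = None) -> list[KsPeak]:
    """Local density maxima with prominence >= ``min_prominence``.

    Default prominence cut is 5% of the maximum density.  Peaks are returned
    sorted by height descending, ties broken toward lower Ks.
    """
    if min_prominence is None:
        min_prominence = 0.05 * float(model.density.max())
    idx, props = signal.find_peaks(model.density, prominence=min_prominence)
    peaks = [
        KsPeak(mode=float(model.grid[i]), height=float(model.density[i]),
               prominence=float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    peaks.sort(key=lambda pk: (-pk.height, pk.mode))
    return peaks


@dataclass(frozen=True)
class RateCalibration:
    """Per-year synonymous rate interval r = Ks_ortho / (2 T) at the two
    calibration-time bounds."""

    ks_ortho_peak: float
    t_min: float
    t_max: float
    r_min: float
    r_max: float

    @classmethod
    def from_rates(cls, r_min: float, r_max: float) -> "RateCalibration":
        """Build a calibration directly from a published rate interval."""
        if not (0 < r_min <= r_max):
            raise ValueError(f"need 0 < r_min <= r_max, got {r_min}, {r_max}")
        return cls(ks_ortho_peak=math.nan, t_min=math.nan, t_max=math.nan,
                   r_min=r_min, r_max=r_max)


def calibrate_rate(ks_ortho_peak: float, t_min: float,
                   t_max: float) -> RateCalibration:
    """Invert r = Ks/(2T) over a divergence-time interval [t_min, t_max] yr."""
    if ks_ortho_peak <= 0:
        raise ValueError(f"ortholog Ks peak must be > 0, got {ks_ortho_peak}")
    if not (0 < t_min < t_max):
        raise ValueError(f"need 0 < t_min < t_max, got {t_min}, {t_max}")
    return RateCalibration(
        ks_ortho_peak=ks_ortho_peak,
        t_min=t_min,
        t_max=t_max,
        r_min=ks_ortho_peak / (2.0 * t_max),
        r_max=ks_ortho_peak / (2.0 * t_min),
    )


@dataclass(frozen=True)
class WgdAgeEstimate:
    ks_wgd_peak: float
    age_min_years: float
    age_max_years: float

    @property
    def age_min_my(self) -> float:
        return round(self.age_min_years / _YEARS_PER_MY, 2)

    @property
    def age_max_my(self) -> float:
        return round(self.age_max_years / _YEARS_PER_MY, 2)


def date_wgd(ks_wgd_peak: float, cal: RateCalibration) -> WgdAgeEstimate:
    """Date a WGD Ks peak with T = Ks/(2r) over the calibrated rate interval.

    The faster rate bound gives the younger age (age_min = Ks / 2 r_max).
    """
    if ks_wgd_peak <= 0:
        raise ValueError(f"WGD Ks peak must be > 0, got {ks_wgd_peak}")
    return WgdAgeEstimate(
        ks_wgd_peak=ks_wgd_peak,
        age_min_years=ks_wgd_peak / (2.0 * cal.r_max),
        age_max_years=ks_wgd_peak / (2.0 * cal.r_min),
    )


def peaks_table(peaks: list[KsPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mode": p.mode, "height": p.height, "prominence": p.prominence}
         for p in peaks],
        columns=["mode", "height", "prominence"],
    )


def dating_table(est: WgdAgeEstimate, cal: RateCalibration) -> pd.DataFrame:
    return pd.DataFrame([{
        "ks_peak": est.ks_wgd_peak,
        "r_min": cal.r_min,
        "r_max": cal.r_max,
        "age_min_MY": est.age_min_my,
        "age_max_MY": est.age_max_my,
    }])
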
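"""Franz diffusion cell analysis: cumulative permeation, flux and Kp.

A Franz cell exposes a membrane to a donor formulation above and a
stirred receptor below; the receptor is sampled over time, with each
withdrawn aliquot replaced by fresh permeant-free medium.  The measured
receptor concentrations therefore under-report the mass that has crossed
the membrane, and must be corrected for previous sample removal:

    Q_n = (V_r * C_n + V_s * sum_{i<n} C_i) / A        [ug cm^-2]

Steady-state flux J is the slope of the linear portion of Q(t); the
permeability coefficient is Kp = J / C_donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "FranzCellSeries",
    "PermeationResult",
    "cumulative_per_area",
    "estimate_flux",
    "permeability_coefficient",
]

MIN_WINDOW_POINTS = 4


@dataclass
class FranzCellSeries:
    """Timed receptor concentrations plus cell geometry.

    times in hours (strictly increasing), concentrations in ug/mL,
    volumes in mL, area in cm^2.  ``donor_concentration`` is the donor
    (saturation) concentration in ug/mL, if known.
    """

    times: np.ndarray
    concentrations: np.ndarray
    receptor_volume: float
    sample_volume: float
    area: float
    donor_concentration: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times) == 0:
            raise ValueError("empty series")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("negative receptor concentration")
        if not (0 <= self.sample_volume < self.receptor_volume):
            raise ValueError("need 0 <= sample_volume < receptor_volume")
        if self.area <= 0:
            raise ValueError("diffusional area must be positive")


@dataclass
class PermeationResult:
    flux: float                      # ug cm^-2 h^-1
    kp: Optional[float]              # cm h^-1, None when donor conc unknown
    window: tuple[int, int]          # [start, end) indices of the fitted portion
    r2_fit: float
    lag_time: float                  # t-intercept of the fitted line, h
    cumulative: np.ndarray = field(repr=False)  # ug cm^-2 per timepoint
    stderr: float = float("nan")     # OLS slope standard error


def cumulative_per_area(s: FranzCellSeries) -> np.ndarray:
    """Sampling-corrected cumulative amount permeated per unit area."""
    c = s.concentrations
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return (s.receptor_volume * c + s.sample_volume * prior) / s.area


def _window_r2(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, r^2 and slope SE of an OLS fit.

    A window with zero variance in Q carries no linear signal: its r^2 is
    defined as 0 so flat (lag) stretches never win the window search.
    """
    if np.ptp(q) == 0.0:
        return 0.0, float(q[0]), 0.0, 0.0
    res = stats.linregress(t, q)
    return res.slope, res.intercept, res.rvalue**2, res.stderr


def estimate_flux(
    s: FranzCellSeries,
    window: Optional[tuple[int, int]] = None,
    min_points: int = MIN_WINDOW_POINTS,
) -> PermeationResult:
    """Estimate steady-state flux from the linear portion of Q(t).

    By default the linear portion is the contiguous window of at least
    ``min_points`` timepoints maximizing the fit r^2; ties prefer the
    longer, then the later window.  Pass ``window=(start, end)`` (end
    exclusive) to override with a fixed published choice.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    n = len(s.times)
    if n < max(min_points, 2):
        raise ValueError(f"need at least {min_points} timepoints, have {n}")
    q = cumulative_per_area(s)
    t = s.times

    if window is not None:
        lo, hi = window
        if not (0 <= lo < hi <= n) or hi - lo < 2:
            raise ValueError(f"invalid fixed window {window!r}")
        best = (lo, hi)
        slope, intercept, r2, se = _window_r2(t[lo:hi], q[lo:hi])
    else:
        # exhaustive search over contiguous windows; series are short
        best_key = None
        best = None
        slope = intercept = r2 = se = 0.0
        for lo in range(0, n - min_points + 1):
            for hi in range(lo + min_points, n + 1):
                sl, ic, rr, ss = _window_r2(t[lo:hi], q[lo:hi])
                key = (round(rr, 10), hi - lo, lo)
                if best_key is None or key > best_key:
                    best_key, best = key, (lo, hi)
                    slope, intercept, r2, se = sl, ic, rr, ss
    kp = None
    if s.donor_concentration is not None:
        kp = permeability_coefficient(slope, s.donor_concentration)
    lag = -intercept / slope if slope != 0 else float("nan")
    return PermeationResult(
        flux=slope, kp=kp, window=best, r2_fit=r2, lag_time=lag,
        cumulative=q, stderr=se,
    )


def permeability_coefficient(flux: float, donor_concentration: float) -> float:
    """Kp = J / C_donor (cm h^-1)."""
    if donor_concentration <= 0:
        raise ValueError("donor concentration must be positive")
    return flux / donor_concentration


def read_series_csv(
    path,
    receptor_volume: float,
    sample_volume: float,
    area: float,
    donor_concentration: Optional[float] = None,
) -> FranzCellSeries:
    """Read a time/concentration CSV (columns time_h, conc_ug_per_ml)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"time_h", "conc_ug_per_ml"} - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    return FranzCellSeries(
        times=df["time_h"].to_numpy(float),
        concentrations=df["conc_ug_per_ml"].to_numpy(float),
        receptor_volume=receptor_volume,
        sample_volume=sample_volume,
        area=area,
        donor_concentration=donor_concentration,
    )
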
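"""Heat as a tracer: diurnal amplitude profiles and vertical streambed flux.

Temperature lances record the propagation of the diurnal surface temperature
signal into saturated streambed sediments.  Downward water flow (downwelling,
DW) carries the signal deeper; upward flow (upwelling, UW) damps it faster
than conduction alone.  The one-dimensional conduction–advection equation

    dT/dt = kappa_e * d2T/dz2 - v * dT/dz

with sinusoidal surface forcing of period ``P`` admits a solution whose
amplitude decays with depth as ``A(z) = A0 * exp(z * (v - p) / (2 kappa_e))``
where ``p = sqrt((alpha + v^2) / 2)`` and
``alpha = sqrt(v^4 + (8 pi kappa_e / P)^2)``.  Inverting the amplitude ratio
of two sensors for the thermal front velocity ``v`` is the Hatch amplitude
method.  Sign convention: ``z`` positive downward, the sediment–water
interface at ``z = 0``, so positive ``v`` means downwelling.

Units: depths in cm in the data model, metres inside the physics; ``kappa_e``
in m^2/day, ``v`` in m/day, period in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TemperatureSeries",
    "HarmonicFit",
    "ThermalParams",
    "FluxEstimate",
    "SiteClassification",
    "hatch_exponent",
    "hatch_amplitude_factor",
    "stallman_phase_lag",
    "fit_diurnal_harmonic",
    "thermal_extinction_depth",
    "solve_hatch_velocity",
    "flux_profile",
    "classify_site",
]

#: Sensor resolution of the thermal lances (deg C); amplitudes below this are
#: treated as undetectable.
DEFAULT_AMPLITUDE_THRESHOLD = 0.04


@dataclass
class TemperatureSeries:
    """Regular temperature time series of one sensor.

    ``depth_cm`` is signed (positive downward, interface at 0).  Timestamps
    must be strictly increasing and equally spaced; missing records are not
    filled in — construct flags gaps instead.
    """

    site_id: str
    depth_cm: float
    time: pd.DatetimeIndex
    temp_c: np.ndarray
    cadence_min: float = field(init=False)
    has_gaps: bool = field(init=False)

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if len(self.time) != len(self.temp_c):
            raise ValueError("time and temp_c must have equal length")
        if len(self.time) >= 2:
            steps = np.diff(self.time.view("int64"))
            if np.any(steps <= 0):
                raise ValueError(
                    f"timestamps not strictly increasing for site "
                    f"{self.site_id!r} depth {self.depth_cm}"
                )
            step = steps.min()
            self.cadence_min = step / 60e9
            self.has_gaps = bool(np.any(steps != step))
        else:
            self.cadence_min = float("nan")
            self.has_gaps = False
        if self.cadence_min == self.cadence_min and self.cadence_min > 0:
            per_day = 1440.0 / self.cadence_min
            if abs(per_day - round(per_day)) > 1e-9:
                raise ValueError("cadence must divide one day")


@dataclass(frozen=True)
class HarmonicFit:
    """Daily harmonic fit ``T = mean + A cos(w t - phase)`` for one window."""

    site_id: str
    depth_cm: float
    window_start: pd.Timestamp
    mean_t: float
    amplitude: float
    phase: float
    rmse: float
    n_obs: int


@dataclass(frozen=True)
class ThermalParams:
    """Physical parameters of the Hatch amplitude relation.

    ``gamma`` is the ratio of the volumetric heat capacity of the saturated
    medium to that of water; it converts thermal front velocity to Darcy
    flux (``q = v * gamma``).
    """

    kappa_e: float = 0.05  # effective thermal diffusivity, m^2/day
    period_days: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_e <= 0 or self.period_days <= 0 or self.gamma <= 0:
            raise ValueError("kappa_e, period_days and gamma must be > 0")


@dataclass(frozen=True)
class FluxEstimate:
    site_id: str
    upper_z: float  # cm
    lower_z: float  # cm
    window_start: pd.Timestamp
    amplitude_ratio: float
    velocity_v: float  # m/day, thermal front, positive downward
    darcy_flux_q: float  # m/day
    converged: bool


@dataclass(frozen=True)
class SiteClassification:
    site_id: str
    mean_velocity: float
    condition: str  # "UW" | "DW" | "indeterminate"
    extinction_interval: tuple[float, float] | None
    n_estimates: int


# ---------------------------------------------------------------------------
# Hatch amplitude relation
# ---------------------------------------------------------------------------

def hatch_exponent(v: float, dz_m: float, kappa_e: float, period_days: float) -> float:
    """Log amplitude ratio over a vertical separation ``dz_m``.

    Returns ``(dz / (2 kappa_e)) * (v - sqrt((alpha + v^2)/2))`` with
    ``alpha = sqrt(v^4 + (8 pi kappa_e / P)^2)``.  Always <= 0 for dz > 0:
    the diurnal amplitude never grows with depth.
    """
    alpha = np.sqrt(v**4 + (8.0 * np.pi * kappa_e / period_days) ** 2)
    return (dz_m / (2.0 * kappa_e)) * (v - np.sqrt((alpha + v**2) / 2.0))


def hatch_amplitude_factor(z_m, v: float, kappa_e: float, period_days: float):
    """Amplitude decay factor f(z) relative to the interface (z in metres)."""
    return np.exp(hatch_exponent(v, np.asarray(z_m, dtype=float), kappa_e, period_days))


def stallman_phase_lag(z_m, v: float, kappa_e: float, period_days: float):
    """Phase lag (radians) of the diurnal signal at depth z (metres).

    From the same complex wavenumber as the amplitude law:
    ``phi(z) = (z / (2 kappa_e)) * sqrt((alpha - v^2)/2)``.
    """
    alpha = np.sqrt(v**4 + (8.0 * np.pi * kappa_e / period_days) ** 2)
    return (np.asarray(z_m, dtype=float) / (2.0 * kappa_e)) * np.sqrt(
        (alpha - v**2) / 2.0
    )


# ---------------------------------------------------------------------------
# Harmonic amplitude extraction
# ---------------------------------------------------------------------------

def fit_diurnal_harmonic(
    series: TemperatureSeries,
    min_samples: int = 24,
) -> list[HarmonicFit]:
    """Fit ``T = m + a cos(wt) + b sin(wt)`` per calendar-day window.

    ``w = 2 pi / day``; within each window the amplitude is
    ``sqrt(a^2 + b^2)`` and the phase ``atan2(b, a)`` (so that
    ``T = m + A cos(wt - phase)``, a positive phase meaning the peak lags
    midnight-referenced forcing, consistent with the downward-propagating
    signal), with ``t`` measured in days from the window's midnight.
    Windows with fewer than ``min_samples`` records are skipped.
    """
    if len(pd.unique(series.time)) < 3:
        raise ValueError("need at least 3 distinct timestamps for a harmonic fit")
    fits: list[HarmonicFit] = []
    days = series.time.normalize()
    frame_t = np.asarray(series.time.view("int64")) / 86400e9  # days since epoch
    omega = 2.0 * np.pi
    for day in pd.unique(days):
        mask = days == day
        n = int(mask.sum())
        if n < min_samples:
            continue
        day = pd.Timestamp(day)
        t = frame_t[mask] - day.value / 86400e9
        y = series.temp_c[mask]
        design = np.column_stack(
            [np.ones_like(t), np.cos(omega * t), np.sin(omega * t)]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        m, a, b = coef
        resid = y - design @ coef
        fits.append(
            HarmonicFit(
                site_id=series.site_id,
                depth_cm=series.depth_cm,
                window_start=pd.Timestamp(day),
                mean_t=float(m),
                amplitude=float(np.hypot(a, b)),
                phase=float(np.arctan2(b, a)),
                rmse=float(np.sqrt(np.mean(resid**2))),
                n_obs=n,
            )
        )
    return fits


def mean_amplitude_profile(fits: Sequence[HarmonicFit]) -> pd.DataFrame:
    """Window-averaged amplitude and mean temperature per (site, depth)."""
    frame = pd.DataFrame(
        {
            "site_id": [f.site_id for f in fits],
            "depth_cm": [f.depth_cm for f in fits],
            "amplitude": [f.amplitude for f in fits],
            "mean_t": [f.mean_t for f in fits],
        }
    )
    out = (
        frame.groupby(["site_id", "depth_cm"], as_index=False)[["amplitude", "mean_t"]]
        .mean()
        .sort_values(["site_id", "depth_cm"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def thermal_extinction_depth(
    fits: Sequence[HarmonicFit],
    threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
) -> tuple[float, float] | None:
    """Locate the sensor pair bracketing the loss of the diurnal signal.

    Amplitudes are averaged over windows per depth, depths scanned from
    shallow to deep; the extinction interval is the pair of adjacent sensor
    depths between which the mean amplitude first drops below ``threshold``
    (default: the 0.04 deg C sensor resolution).  Returns ``None`` when the
    signal is detectable at every sensor (extinction deeper than the lance).
    """
    profile = mean_amplitude_profile(fits)
    if profile["site_id"].nunique() > 1:
        raise ValueError("extinction depth is computed per site; got several sites")
    depths = profile["depth_cm"].to_numpy()
    if len(depths) < 2:
        raise ValueError("need fits at >= 2 distinct depths")
    amps = profile["amplitude"].to_numpy()
    below = amps < threshold
    if not below.any():
        return None
    first = int(np.argmax(below))
    if first == 0:
        # no detectable signal even at the shallowest sensor
        return (depths[0], depths[0])
    return (float(depths[first - 1]), float(depths[first]))


# ---------------------------------------------------------------------------
# Inverse problem
# ---------------------------------------------------------------------------

def solve_hatch_velocity(
    amplitude_ratio: float,
    dz_m: float,
    params: ThermalParams,
    v_bracket: tuple[float, float] = (-10.0, 10.0),
    gtol: float = 1e-10,
) -> float:
    """Invert the amplitude ratio of a sensor pair for thermal front velocity.

    Solves ``g(v) = ln(Ar) - hatch_exponent(v, dz) = 0`` by Brent's method.
    The exponent is strictly increasing in ``v``, so the root is unique and
    increases monotonically with ``Ar``.

    Parameters
    ----------
    amplitude_ratio : ratio ``A_lower / A_upper`` in (0, 1).
    dz_m : sensor separation in metres (> 0).
    """
    if not 0.0 < amplitude_ratio < 1.0:
        raise ValueError(f"amplitude ratio must be in (0, 1), got {amplitude_ratio}")
    if dz_m <= 0:
        raise ValueError("dz_m must be > 0")
    log_ar = np.log(amplitude_ratio)

    def g(v: float) -> float:
        return log_ar - hatch_exponent(v, dz_m, params.kappa_e, params.period_days)

    lo, hi = v_bracket
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if np.sign(glo) == np.sign(ghi):
        raise RuntimeError(
            f"no sign change in bracket {v_bracket}: g({lo})={glo:.3g}, "
            f"g({hi})={ghi:.3g}; amplitude ratio {amplitude_ratio:.6g} over "
            f"dz={dz_m} m is outside the physical range for these parameters"
        )
    root = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(g(root)) > gtol:
        raise RuntimeError(f"root residual {g(root):.3g} exceeds tolerance {gtol}")
    return float(root)


def flux_profile(
    fits: Sequence[HarmonicFit],
    params: ThermalParams,
    amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
) -> list[FluxEstimate]:
    """Per-window Hatch velocity for every adjacent sub-surface sensor pair.

    Pairs where either amplitude is below the detectability threshold, or
    where the ratio is not in (0, 1), are returned flagged ``converged=False``
    (velocity NaN) so that downstream means can exclude them explicitly.
    """
    frame = pd.DataFrame(
        {
            "site_id": [f.site_id for f in fits],
            "depth_cm": [f.depth_cm for f in fits],
            "window_start": [f.window_start for f in fits],
            "amplitude": [f.amplitude for f in fits],
        }
    )
    frame = frame[frame["depth_cm"] > 0]
    if frame["depth_cm"].nunique() < 2:
        raise ValueError("need harmonic fits at >= 2 sub-surface depths")
    estimates: list[FluxEstimate] = []
    for (site, window), grp in frame.groupby(["site_id", "window_start"], sort=True):
        grp = grp.sort_values("depth_cm", kind="mergesort")
        depths = grp["depth_cm"].to_numpy()
        amps = grp["amplitude"].to_numpy()
        for upper, lower, a_up, a_lo in zip(depths, depths[1:], amps, amps[1:]):
            ratio = a_lo / a_up if a_up > 0 else np.inf
            ok = a_up >= amplitude_threshold and a_lo >= amplitude_threshold
            ok = ok and 0.0 < ratio < 1.0
            v = np.nan
            if ok:
                try:
                    v = solve_hatch_velocity(ratio, (lower - upper) / 100.0, params)
                except RuntimeError:
                    ok = False
            estimates.append(
                FluxEstimate(
                    site_id=site,
                    upper_z=float(upper),
                    lower_z=float(lower),
                    window_start=window,
                    amplitude_ratio=float(ratio),
                    velocity_v=float(v),
                    darcy_flux_q=float(v * params.gamma) if ok else np.nan,
                    converged=bool(ok),
                )
            )
    return estimates


def classify_site(
    profile: Sequence[FluxEstimate],
    tol: float = 0.01,
    extinction_interval: tuple[float, float] | None = None,
) -> SiteClassification:
    """Classify a site as upwelling/downwelling from its mean velocity.

    The site mean is the average thermal front velocity over all converged
    pair-window estimates.  ``condition`` is DW when the mean exceeds
    ``+tol`` (m/day), UW below ``-tol``, otherwise indeterminate.
    """
    sites = {e.site_id for e in profile}
    if len(sites) != 1:
        raise ValueError("classify_site expects estimates for exactly one site")
    vs = np.array([e.velocity_v for e in profile if e.converged])
    if vs.size == 0:
        raise ValueError(f"no converged flux estimates for site {sites.pop()!r}")
    mean_v = float(vs.mean())
    if mean_v > tol:
        condition = "DW"
    elif mean_v < -tol:
        condition = "UW"
    else:
        condition = "indeterminate"
    return SiteClassification(
        site_id=sites.pop(),
        mean_velocity=mean_v,
        condition=condition,
        extinction_interval=extinction_interval,
        n_estimates=int(vs.size),
    )
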
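"""Detector-characterization pipeline stages.

Three studies quantify how far the scintillator departs from an ideal
water-equivalent point detector:

* **Energy dependence** — a measured away-along grid, stem-corrected and
  normalized at a reference point, is compared node by node with the
  consensus dose-rate table; the Ir-192 spectrum softens with distance,
  so any residual spectral sensitivity shows up as a radial trend.
* **Angular dependence** — net response versus source angle in the axial
  plane (perpendicular to the scintillator axis) and the azimuthal plane
  (containing the axis), summarized as percent deviations about the
  sweep mean.
* **Temperature dependence** — scintillation light output falls linearly
  with probe temperature; a straight-line fit S(T) = S0 * (1 + a (T-T0))
  yields the coefficient ``a`` used to correct measurements taken at
  body temperature against a room-temperature calibration.

Percent-difference summaries report mean and SD of the *magnitudes* of
the per-point deviations; the signed values are kept for plotting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signals import CorrectedSignal
from .tg43 import AwayAlongTable, DosePoint, dose_rate_at

__all__ = [
    "ComparisonStats",
    "TemperatureModel",
    "AngularSweep",
    "FitError",
    "away_along_comparison",
    "angular_summary",
    "fit_temperature_model",
    "temperature_correction",
    "relative_response",
]


class FitError(ValueError):
    """Raised when a model fit is impossible (too few or degenerate data)."""


def _abs_stats(pcts: np.ndarray) -> tuple[float, float, float]:
    mags = np.abs(pcts)
    mean = float(mags.mean())
    sd = float(mags.std(ddof=1)) if mags.size > 1 else 0.0
    return mean, sd, float(mags.max())


@dataclass
class ComparisonStats:
    """Summary of per-point percent deviations.

    ``mean_pct``/``sd_pct`` are computed over the magnitudes |pct|;
    ``per_point`` keeps the signed values with their geometry.
    """

    mean_pct: float
    sd_pct: float
    max_abs_pct: float
    per_point: list[tuple[DosePoint | float, float]]
    z0_mean_pct: float | None = None
    z0_sd_pct: float | None = None
    per_away_max: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.per_point:
            raise ValueError("per_point must be non-empty")
        if self.max_abs_pct < 0:
            raise ValueError("max_abs_pct must be >= 0")


@dataclass
class TemperatureModel:
    """Linear temperature response S(T)/S(T0) = 1 + a (T - T0).

    ``a`` is the fractional temperature coefficient in 1/degC (so
    100*a is the %/degC figure), ``s0`` the signal at the reference
    temperature ``t0`` and ``u_a`` the k=1 uncertainty of the slope.
    """

    a: float
    t0: float = 25.0
    s0: float = 1.0
    u_a: float = 0.0
    fitted_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        if abs(self.a) >= 0.05:
            raise ValueError(
                f"|a| = {abs(self.a):.3g}/degC exceeds the 0.05/degC sanity bound"
            )
        if self.u_a < 0:
            raise ValueError("u_a must be >= 0")


@dataclass
class AngularSweep:
    """Stem-corrected net rates over a source-angle sweep at fixed radius."""

    plane: str
    angles: np.ndarray
    net_rates: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.plane not in ("axial", "azimuthal"):
            raise ValueError(f"plane must be 'axial' or 'azimuthal', got {self.plane!r}")
        self.angles = np.asarray(self.angles, dtype=float)
        self.net_rates = np.asarray(self.net_rates, dtype=float)
        if self.angles.size != self.net_rates.size:
            raise ValueError("angles and net_rates must have the same length")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any((self.angles < 0) | (self.angles >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @classmethod
    def from_signals(
        cls, signals: Sequence[CorrectedSignal], plane: str, radius: float
    ) -> "AngularSweep":
        pairs = sorted(
            ((float(s.geometry), s.net_rate) for s in signals), key=lambda p: p[0]
        )
        ang, rates = zip(*pairs)
        return cls(plane=plane, angles=np.array(ang), net_rates=np.array(rates), radius=radius)


def away_along_comparison(
    measured: Sequence[CorrectedSignal],
    reference: AwayAlongTable,
    sk: float = 1.0,
) -> ComparisonStats:
    """Node-by-node comparison of a normalized measured grid with the
    reference away-along table.

    Per point: pct = 100 * (measured - reference) / reference.  Besides
    the overall magnitude summary, the z = 0 radial profile is
    summarized separately and the maximum |pct| of each z-profile
    (per away distance) is reported.
    """
    per_point: list[tuple[DosePoint | float, float]] = []
    for s in measured:
        if not isinstance(s.geometry, DosePoint):
            raise TypeError("away-along comparison requires DosePoint geometries")
        ref = dose_rate_at(reference, s.geometry, sk)
        per_point.append((s.geometry, 100.0 * (s.net_rate - ref) / ref))
    if not per_point:
        raise ValueError("no measured points overlap the reference table")
    pcts = np.array([p for _, p in per_point])
    mean, sd, mx = _abs_stats(pcts)

    z0 = np.array([p for g, p in per_point if abs(g.z) < 1e-9])
    z0_mean = z0_sd = None
    if z0.size:
        z0_mean, z0_sd, _ = _abs_stats(z0)

    per_away: dict[float, float] = {}
    for g, p in per_point:
        per_away[g.y] = max(per_away.get(g.y, 0.0), abs(p))

    return ComparisonStats(
        mean_pct=mean,
        sd_pct=sd,
        max_abs_pct=mx,
        per_point=per_point,
        z0_mean_pct=z0_mean,
        z0_sd_pct=z0_sd,
        per_away_max=per_away,
    )


def angular_summary(sweep: AngularSweep) -> ComparisonStats:
    """Percent response variation over an angular sweep.

    Deviations are taken about the mean response of the sweep (no angle
    is singled out as reference); the summary is the mean and SD of the
    deviation magnitudes.
    """
    if sweep.angles.size < 2:
        raise ValueError("need at least two angles")
    mean_resp = sweep.net_rates.mean()
    if mean_resp == 0:
        raise ValueError("mean response is zero")
    pcts = 100.0 * (sweep.net_rates / mean_resp - 1.0)
    mean, sd, mx = _abs_stats(pcts)
    per_point = [(float(a), float(p)) for a, p in zip(sweep.angles, pcts)]
    return ComparisonStats(mean_pct=mean, sd_pct=sd, max_abs_pct=mx, per_point=per_point)


def fit_temperature_model(
    temps: Sequence[float],
    signals: Sequence[float],
    t0: float = 25.0,
    u_temps: Sequence[float] | float | None = None,
) -> TemperatureModel:
    """Ordinary least squares of signal versus temperature, reparameterized
    to (s0 at t0, a = slope / s0).

    ``u_temps`` (degC, k=1; scalar or per-point) adds a Type B slope
    contribution |slope| * u_T / sqrt(Sxx) in quadrature with the fit
    standard error before converting to the fractional coefficient.
    The fit is unweighted: repeats at each temperature enter as
    individual points.
    """
    x = np.asarray(temps, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size != y.size:
        raise FitError("temps and signals must have the same length")
    if np.unique(x).size < 3:
        raise FitError("need >= 3 distinct temperatures")
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise FitError("zero temperature spread")
    slope = float(((x - xbar) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    dof = x.size - 2
    s2 = float((resid**2).sum() / dof) if dof > 0 else 0.0
    se_slope = math.sqrt(s2 / sxx)

    s0 = intercept + slope * t0
    if s0 <= 0:
        raise FitError(f"fitted signal at t0={t0} is non-positive ({s0:.3g})")
    a = slope / s0

    u_slope_b = 0.0
    if u_temps is not None:
        u_x = float(np.mean(np.atleast_1d(np.asarray(u_temps, dtype=float))))
        u_slope_b = abs(slope) * u_x / math.sqrt(sxx)
    u_a = math.hypot(se_slope, u_slope_b) / s0

    return TemperatureModel(
        a=a,
        t0=t0,
        s0=s0,
        u_a=u_a,
        fitted_range=(float(x.min()), float(x.max())),
    )


def relative_response(model: TemperatureModel, t: float) -> float:
    """S(T)/S(T0) = 1 + a (T - T0)."""
    return 1.0 + model.a * (t - model.t0)


def temperature_correction(model: TemperatureModel, t_meas: float) -> float:
    """Multiplicative correction restoring the T0-equivalent response:
    1 / (1 + a (t_meas - t0)).

    Warns when ``t_meas`` lies more than 5 degC outside the fitted range.
    """
    if model.fitted_range is not None:
        lo, hi = model.fitted_range
        if not (lo - 5.0 <= t_meas <= hi + 5.0):
            warnings.warn(
                f"t_meas={t_meas} degC is outside the fitted range "
                f"[{lo}, {hi}] degC by more than 5 degC; the linear model "
                "is extrapolating",
                stacklevel=2,
            )
    rel = relative_response(model, t_meas)
    if rel <= 0:
        raise ValueError(
            f"1 + a*(t - t0) = {rel:.3g} <= 0: linear model invalid at {t_meas} degC"
        )
    return 1.0 / rel
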
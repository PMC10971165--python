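"""Synthetic measurement generator.

Emulates the three characterization set-ups — away-along grid scans,
angular sweeps at fixed radius, and constant-geometry irradiations at
varying water temperature — for a scintillating-fiber probe next to an
Ir-192 HDR source.  Every physical dependence is injected explicitly
(energy and angular perturbation profiles, a linear temperature slope,
an additive stem term, counting noise), so each pipeline stage can be
validated by round-tripping known inputs.

The probe model is::

    psd_rate  = sensitivity * dose_rate * energy_profile(r)
                * angular_profile(angle) * (1 + a (T - 25)) + stem
    dummy_rate = stem

with the stem term proportional to an inverse-square-weighted integral
over the irradiated fiber length (the Cherenkov/fluorescence light
scales with how close the source sits to the fiber axis, peaking near
0/360 degrees in the azimuthal plane and staying constant in the axial
plane).

Defaults reflect the study conditions: a 10 s exposure per acquisition,
count rates of order 10^3 per 100 ms at 4 cm from a 38.3 mGy.m2/h
source, a -0.19 %/degC temperature slope, azimuthal/axial sweeps from
30 to 330 degrees in 20-degree steps at 60 mm, and temperature sets of
five irradiations at 5 degC steps over 15-40 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Literal, Sequence

import numpy as np

from .signals import Acquisition, MeasurementSession
from .tg43 import (
    AwayAlongTable,
    DosePoint,
    SourceState,
    dose_rate_at,
    geometry_function_line,
    mm_to_cm,
)
from .uncertainty import TemperatureReading

__all__ = [
    "GeneratorConfig",
    "make_toy_away_along",
    "simulate_away_along_session",
    "simulate_angular_session",
    "simulate_temperature_session",
    "ANGULAR_SWEEP_DEG",
    "TEMPERATURE_SET_POINTS_C",
]

#: Source angles of the angular-dependence protocol: 30..330 deg, 20-deg steps.
ANGULAR_SWEEP_DEG = tuple(range(30, 331, 20))

#: Water set points of the temperature protocol: 15..40 degC, 5-degC steps.
TEMPERATURE_SET_POINTS_C = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)

#: Session start used for synthetic timestamps.
_EPOCH = datetime(2024, 3, 20, 9, 0, 0)

#: Dose-rate constant of the toy source model, cGy/(h.U) at 1 cm on the
#: transverse axis.
TOY_DOSE_RATE_CONSTANT = 1.109

#: Thermometer calibration uncertainty, degC at k=1 (certificate 0.09 degC
#: at k=2).
THERMOMETER_U_CAL = 0.045


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic detector.

    sensitivity is in counts per cGy absorbed in the scintillator;
    stem_coefficient in counts per 100 ms per (U * cm^-1) of
    inverse-square-weighted irradiated fiber; temp_slope is the
    fractional response change per degC.  Profiles are callables
    (radius_cm -> factor, angle_deg -> factor); ``None`` means
    identically 1.
    """

    seed: int = 0
    sensitivity: float = 1.4e4
    temp_slope: float = -0.0019
    stem_coefficient: float = 0.004
    energy_profile: Callable[[float], float] | None = None
    angular_profile: Callable[[float], float] | None = None
    noise_model: Literal["poisson", "gaussian", "none"] = "poisson"
    gaussian_pct: float = 0.3
    exposure_s: float = 10.0
    fiber_len_cm: float = 15.0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def _energy(self, r: float) -> float:
        return 1.0 if self.energy_profile is None else float(self.energy_profile(r))

    def _angular(self, angle: float) -> float:
        return 1.0 if self.angular_profile is None else float(self.angular_profile(angle))


def _apply_noise(rng: np.random.Generator, rate: float, duration: float, cfg: GeneratorConfig) -> float:
    if cfg.noise_model == "none" or rate <= 0:
        return rate
    if cfg.noise_model == "poisson":
        windows = duration / 0.1
        return float(rng.poisson(rate * windows)) / windows
    return rate * (1.0 + rng.normal(0.0, cfg.gaussian_pct / 100.0))


def make_toy_away_along(
    away: Sequence[float] | None = None,
    along: Sequence[float] | None = None,
    source: SourceState | None = None,
    dose_rate_constant: float = TOY_DOSE_RATE_CONSTANT,
    mu: float = 0.01,
) -> AwayAlongTable:
    """Deterministic toy away-along table.

    Values are ``Lambda * G(r, theta) / G(1 cm, 90 deg) * exp(-mu (r-1))``
    — the TG-43 geometry function for the source's active length times a
    mild exponential radial attenuation standing in for the radial dose
    function.  ``mu = 0`` with a point source gives an exact 1/r^2 field.

    The default grid covers y in [1, 6] cm and z in [-7, 7] cm at 1 cm
    spacing, the measured ranges of the away-along protocol.
    """
    away_arr = np.arange(1.0, 6.5, 1.0) if away is None else np.asarray(away, float)
    along_arr = np.arange(-7.0, 7.5, 1.0) if along is None else np.asarray(along, float)
    L = 0.0 if source is None else mm_to_cm(source.active_length)
    g_ref = geometry_function_line(1.0, 90.0, L)
    values = np.empty((along_arr.size, away_arr.size))
    for i, z in enumerate(along_arr):
        for j, y in enumerate(away_arr):
            p = DosePoint(y=y, z=z)
            g = geometry_function_line(p.r, p.theta, L)
            values[i, j] = dose_rate_constant * (g / g_ref) * math.exp(-mu * (p.r - 1.0))
    return AwayAlongTable(away=away_arr, along=along_arr, values=values)


# -- stem proxies ---------------------------------------------------------
# Inverse-square-weighted irradiated fiber length: integral of
# 1/(distance to source)^2 along the fiber, in 1/cm.  Any monotone-in-
# proximity model peaking near the fiber axis works for round-trip tests;
# this one has a closed form.


def _stem_proxy_grid(y: float, z: float, fiber_len: float) -> float:
    """Fiber occupies the z-axis segment [0, fiber_len]; source at (y, z)."""
    if y == 0:
        raise ValueError("source on the fiber axis")
    y = abs(y)
    return (math.atan((fiber_len - z) / y) + math.atan(z / y)) / y


def _stem_proxy_azimuthal(angle_deg: float, radius: float, fiber_len: float) -> float:
    """Fiber along the 0-degree direction from the probe tip; source at
    ``radius`` cm and ``angle_deg`` in the plane containing the fiber."""
    phi = math.radians(angle_deg)
    s = radius * math.cos(phi)
    h = radius * abs(math.sin(phi))
    if h < 1e-9 * radius:
        if s < 0:  # source behind the distal tip, on axis
            return 1.0 / abs(s) - 1.0 / (abs(s) + fiber_len)
        raise ValueError("source on the fiber axis")
    return (math.atan((fiber_len - s) / h) + math.atan(s / h)) / h


def _stem_proxy_axial(radius: float, fiber_len: float) -> float:
    """Fiber perpendicular to the axial plane: same for every angle."""
    return math.atan(fiber_len / radius) / radius


def _rate_to_counts(rate: float, duration: float) -> float:
    return rate * duration / 0.1


def simulate_away_along_session(
    cfg: GeneratorConfig,
    table: AwayAlongTable,
    source: SourceState,
    points: Sequence[DosePoint] | None = None,
    step_s: float = 30.0,
) -> tuple[MeasurementSession, MeasurementSession]:
    """Paired PSD and dummy sessions over an away-along grid.

    By default every node of ``table`` is visited.  The dummy session
    repeats the grid immediately after the PSD session.
    """
    if points is None:
        points = [
            DosePoint(y=float(y), z=float(z)) for z in table.along for y in table.away
        ]
    rng = np.random.default_rng(cfg.seed)
    sk = source.sk
    dwell = cfg.exposure_s + step_s

    def build(kind: Literal["psd", "dummy"], t0: datetime) -> MeasurementSession:
        acqs = []
        for i, p in enumerate(points):
            stem = cfg.stem_coefficient * sk * _stem_proxy_grid(p.y, p.z, cfg.fiber_len_cm)
            if kind == "psd":
                dose = dose_rate_at(table, p, sk)  # cGy/h
                rate = (
                    cfg.sensitivity * dose / 36000.0 * cfg._energy(p.r) + stem
                )
            else:
                rate = stem
            rate = _apply_noise(rng, rate, cfg.exposure_s, cfg)
            acqs.append(
                Acquisition(
                    rate=rate,
                    duration=cfg.exposure_s,
                    timestamp=t0 + timedelta(seconds=i * dwell),
                    geometry=p,
                    probe_kind=kind,
                )
            )
        return MeasurementSession(acquisitions=acqs, probe_kind=kind, metadata={"study": "away_along"})

    psd = build("psd", _EPOCH)
    dummy = build("dummy", _EPOCH + timedelta(seconds=len(points) * dwell))
    return psd, dummy


def simulate_angular_session(
    cfg: GeneratorConfig,
    plane: Literal["axial", "azimuthal"],
    source: SourceState,
    radius_mm: float = 60.0,
    angles_deg: Sequence[float] = ANGULAR_SWEEP_DEG,
    dose_rate_constant: float = TOY_DOSE_RATE_CONSTANT,
    step_s: float = 30.0,
) -> tuple[MeasurementSession, MeasurementSession]:
    """Paired PSD and dummy sessions over an angular sweep at fixed radius.

    The dose rate is the same at every angle (point-source model at the
    sweep radius); the azimuthal stem term grows toward the fiber-axis
    angles while the axial one is constant.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    r_cm = mm_to_cm(radius_mm)
    rng = np.random.default_rng(cfg.seed)
    sk = source.sk
    dose = sk * dose_rate_constant / r_cm**2  # cGy/h
    dwell = cfg.exposure_s + step_s

    def stem_at(angle: float) -> float:
        if plane == "azimuthal":
            proxy = _stem_proxy_azimuthal(angle, r_cm, cfg.fiber_len_cm)
        else:
            proxy = _stem_proxy_axial(r_cm, cfg.fiber_len_cm)
        return cfg.stem_coefficient * sk * proxy

    def build(kind: Literal["psd", "dummy"], t0: datetime) -> MeasurementSession:
        acqs = []
        for i, ang in enumerate(angles_deg):
            stem = stem_at(float(ang))
            if kind == "psd":
                rate = cfg.sensitivity * dose / 36000.0 * cfg._angular(float(ang)) + stem
            else:
                rate = stem
            rate = _apply_noise(rng, rate, cfg.exposure_s, cfg)
            acqs.append(
                Acquisition(
                    rate=rate,
                    duration=cfg.exposure_s,
                    timestamp=t0 + timedelta(seconds=i * dwell),
                    geometry=float(ang),
                    probe_kind=kind,
                )
            )
        return MeasurementSession(
            acquisitions=acqs,
            probe_kind=kind,
            metadata={"study": "angular", "plane": plane, "radius_mm": radius_mm},
        )

    psd = build("psd", _EPOCH)
    dummy = build("dummy", _EPOCH + timedelta(seconds=len(list(angles_deg)) * dwell))
    return psd, dummy


def simulate_temperature_session(
    cfg: GeneratorConfig,
    temps: Sequence[float] = TEMPERATURE_SET_POINTS_C,
    n_repeats: int = 5,
    s0_rate: float = 1000.0,
    t0: float = 25.0,
    sensor_drift_c: float = 0.1,
    u_cal: float = THERMOMETER_U_CAL,
    step_s: float = 60.0,
) -> tuple[MeasurementSession, list[TemperatureReading]]:
    """Constant-geometry irradiation sets at varying water temperature.

    For each set point the water temperature is read before and after the
    ``n_repeats`` irradiations (each reading jittered by the sensor-pair
    spread ``sensor_drift_c``); acquisitions carry the set temperature
    (mean of initial and final) and a rate
    ``s0_rate * (1 + temp_slope * (T - t0))`` plus counting noise.

    Returns the PSD session and the per-set temperature readings.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    acqs = []
    readings = []
    t = _EPOCH
    for temp in temps:
        t_init = temp + rng.normal(0.0, sensor_drift_c)
        t_final = temp + rng.normal(0.0, sensor_drift_c)
        readings.append(TemperatureReading(t_initial=t_init, t_final=t_final, u_cal=u_cal))
        set_temp = 0.5 * (t_init + t_final)
        expected = s0_rate * (1.0 + cfg.temp_slope * (set_temp - t0))
        for _ in range(n_repeats):
            rate = _apply_noise(rng, expected, cfg.exposure_s, cfg)
            acqs.append(
                Acquisition(
                    rate=rate,
                    duration=cfg.exposure_s,
                    timestamp=t,
                    geometry=DosePoint(y=4.0, z=0.0),
                    probe_kind="psd",
                    temperature=set_temp,
                )
            )
            t += timedelta(seconds=cfg.exposure_s + step_s)
    return (
        MeasurementSession(acquisitions=acqs, probe_kind="psd", metadata={"study": "temperature"}),
        readings,
    )
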
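"""IAEA TRS-398-derived calibration chain for a compact PMMA phantom.

A Farmer ionization chamber calibrated in absorbed dose to water in a
Co-60 beam is used to measure ionization in a 10 cm x 10 cm cylindrical
PMMA mini-phantom next to an Ir-192 HDR source.  Monte Carlo dose ratios
between that geometry and the TG-43 full-scatter reference geometry (a
40 cm radius water sphere) provide the quality-conversion chain:

    k_Q,Q0 = (D_w / D_air_mean)_Q / (D_w / D_air_mean)_Q0

and a single full-scatter factor F converting the corrected PMMA-phantom
reading directly into absorbed dose to water under TG-43 scatter
conditions:

    D_w,full = N_D,w,Co-60 * M * F
    F = (D_w,full / D_air_mean,PMMA)_Ir-192 / [s_w,air * p]_Co-60

The Co-60 denominator is the tabulated TRS-398 value for the PTW PMMA
Farmer chamber (1.112), not a simulation; it lives in
:class:`TRS398Constants` so a simulated value can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .uncertainty import combine_quadrature

__all__ = [
    "DoseRatioSet",
    "TRS398Constants",
    "ChamberReading",
    "CalibrationResult",
    "quality_factor",
    "full_scatter_factor",
    "correct_reading",
    "dose_to_water_full_scatter",
    "water_equivalence_gap",
    "calibrate",
    "load_mc_ratios",
    "REF_TEMPERATURE_C",
    "REF_PRESSURE_KPA",
]

#: Reference conditions for air density (dry air, TG-43 supplement).
REF_TEMPERATURE_C = 20.0
REF_PRESSURE_KPA = 101.325


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class DoseRatioSet:
    """Monte Carlo dose ratios, full-scatter water sphere over PMMA
    mini-phantom, each with its k=1 relative uncertainty in percent.

    ``dw_full_over_dair_pmma`` is the absolute ratio entering the
    full-scatter factor; when back-derived from a published F it should
    be flagged ``derived=True``.
    """

    dw_full_over_dw_pmma: float
    dair_full_over_dair_pmma: float
    dpol_full_over_dpol_pmma: float
    dw_full_over_dair_pmma: float
    u_dw: float = 0.0
    u_dair: float = 0.0
    u_dpol: float = 0.0
    u_dw_dair: float = 0.0
    derived: bool = False

    def __post_init__(self) -> None:
        _check_positive(
            dw_full_over_dw_pmma=self.dw_full_over_dw_pmma,
            dair_full_over_dair_pmma=self.dair_full_over_dair_pmma,
            dpol_full_over_dpol_pmma=self.dpol_full_over_dpol_pmma,
            dw_full_over_dair_pmma=self.dw_full_over_dair_pmma,
        )
        for name in ("u_dw", "u_dair", "u_dpol", "u_dw_dair"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TRS398Constants:
    """Chamber constants taken from TRS-398 and the calibration certificate.

    ``sw_air_p_co60``: the product [s_w,air * p] for the chamber in the
    Co-60 reference quality (dimensionless; W_air ratio taken as 1).
    ``nd_w_co60``: absorbed-dose-to-water calibration factor, Gy/nC.
    ``u_sw_air_p``: k=1 relative uncertainty of the product, percent.
    """

    sw_air_p_co60: float = 1.112
    nd_w_co60: float = 0.054
    u_sw_air_p: float = 0.8

    def __post_init__(self) -> None:
        if not self.sw_air_p_co60 > 1:
            raise ValueError("sw_air_p_co60 must exceed 1 for a real chamber")
        _check_positive(nd_w_co60=self.nd_w_co60)


@dataclass(frozen=True)
class ChamberReading:
    """Raw electrometer reading with influence quantities."""

    m_raw: float
    temperature: float
    pressure: float
    ks: float = 1.0
    kpol: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(pressure=self.pressure)
        for name in ("ks", "kpol"):
            v = getattr(self, name)
            if not 0.9 < v < 1.1:
                raise ValueError(f"{name}={v} outside the physical band (0.9, 1.1)")


@dataclass(frozen=True)
class CalibrationResult:
    f_factor: float
    k_ir192_pmma: float
    u_rel: float
    dw_full_scatter: float | None = None

    def __post_init__(self) -> None:
        _check_positive(f_factor=self.f_factor, k_ir192_pmma=self.k_ir192_pmma)
        if self.u_rel < 0:
            raise ValueError("u_rel must be >= 0")


def quality_factor(dw_over_dair_q: float, dw_over_dair_q0: float) -> float:
    """Beam-quality conversion k_Q,Q0 from Bragg-Gray dose ratios."""
    _check_positive(
        dw_over_dair_q=dw_over_dair_q, dw_over_dair_q0=dw_over_dair_q0
    )
    return dw_over_dair_q / dw_over_dair_q0


def full_scatter_factor(
    dw_full_over_dair_pmma_ir192: float, constants: TRS398Constants
) -> float:
    """Full-scatter factor F converting the corrected PMMA-phantom reading
    into absorbed dose to water under TG-43 full-scatter conditions."""
    _check_positive(dw_full_over_dair_pmma_ir192=dw_full_over_dair_pmma_ir192)
    return dw_full_over_dair_pmma_ir192 / constants.sw_air_p_co60


def correct_reading(
    rdg: ChamberReading,
    ref_temperature: float = REF_TEMPERATURE_C,
    ref_pressure: float = REF_PRESSURE_KPA,
) -> float:
    """Temperature/pressure/recombination/polarity-corrected reading M."""
    kpt = ((273.15 + rdg.temperature) / (273.15 + ref_temperature)) * (
        ref_pressure / rdg.pressure
    )
    return rdg.m_raw * rdg.ks * rdg.kpol * kpt


def dose_to_water_full_scatter(nd_w: float, m: float, f: float) -> float:
    """D_w in the full-scatter geometry: N_D,w,Co-60 * M * F (Gy)."""
    _check_positive(nd_w=nd_w, f=f)
    if m < 0:
        raise ValueError("corrected reading must be >= 0")
    return nd_w * m * f

def water_equivalence_gap(ratios: DoseRatioSet) -> float:
    """Percent disagreement between the water and polystyrene full/PMMA
    dose ratios — how far polystyrene is from being water-equivalent in
    the Ir-192 spectrum at the calibration distance."""
    return 100.0 * abs(
        ratios.dw_full_over_dw_pmma / ratios.dpol_full_over_dpol_pmma - 1.0
    )


def calibrate(
    ratios: DoseRatioSet,
    constants: TRS398Constants | None = None,
    reading: ChamberReading | None = None,
    ref_temperature: float = REF_TEMPERATURE_C,
    ref_pressure: float = REF_PRESSURE_KPA,
) -> CalibrationResult:
    """Full calibration chain: F, the PMMA-phantom quality factor, the
    combined k=1 relative uncertainty and (if a reading is supplied) the
    absorbed dose to water in full-scatter conditions.

    The uncertainty of F combines, in quadrature, the Monte Carlo
    uncertainty of the numerator ratio with the TRS-398 uncertainty of
    the Co-60 denominator.
    """
    if constants is None:
        constants = TRS398Constants()
    f = full_scatter_factor(ratios.dw_full_over_dair_pmma, constants)
    # (Dw/Dair)_PMMA,Ir-192 is not tabulated directly; recover it from the
    # absolute ratio and the per-material full/PMMA ratio.
    dw_over_dair_pmma = ratios.dw_full_over_dair_pmma / ratios.dw_full_over_dw_pmma
    k = quality_factor(dw_over_dair_pmma, constants.sw_air_p_co60)
    u_rel = combine_quadrature([ratios.u_dw_dair, constants.u_sw_air_p])
    dw = None
    if reading is not None:
        m = correct_reading(reading, ref_temperature, ref_pressure)
        dw = dose_to_water_full_scatter(constants.nd_w_co60, m, f)
    return CalibrationResult(
        f_factor=f, k_ir192_pmma=k, u_rel=u_rel, dw_full_scatter=dw
    )


def load_mc_ratios(path: str | Path | None = None) -> DoseRatioSet:
    """Load the bundled (or a user-supplied) Monte Carlo dose-ratio file."""
    if path is None:
        text = (
            resources.files("ivdkit").joinpath("data/mc_ratios.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)

    def val(key: str) -> float:
        return float(raw[key]["value"])

    def unc(key: str) -> float:
        return float(raw[key].get("u_rel_pct", 0.0))

    return DoseRatioSet(
        dw_full_over_dw_pmma=val("dw_full_over_dw_pmma"),
        dair_full_over_dair_pmma=val("dair_full_over_dair_pmma"),
        dpol_full_over_dpol_pmma=val("dpol_full_over_dpol_pmma"),
        dw_full_over_dair_pmma=val("dw_full_over_dair_pmma"),
        u_dw=unc("dw_full_over_dw_pmma"),
        u_dair=unc("dair_full_over_dair_pmma"),
        u_dpol=unc("dpol_full_over_dpol_pmma"),
        u_dw_dair=unc("dw_full_over_dair_pmma"),
        derived=bool(raw["dw_full_over_dair_pmma"].get("derived", False)),
    )
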
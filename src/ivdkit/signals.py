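"""Raw-signal processing for scintillator and dummy probes.

A plastic-scintillator probe reads dose-proportional light plus a stem
signal (Cherenkov and fluorescence generated in the optical fiber
itself); a dummy probe — identical fiber, no scintillator — reads the
stem signal alone.  Subtracting paired acquisitions isolates the
scintillation signal.  The corrected rates are then put on a common
source-strength scale (decay normalization) and anchored to a reference
dose-rate table at a chosen point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .tg43 import AwayAlongTable, DosePoint, SourceState, decay_correct, dose_rate_at

__all__ = [
    "Acquisition",
    "CorrectedSignal",
    "MeasurementSession",
    "GeometryMismatchError",
    "subtract_stem",
    "decay_normalize",
    "normalize_to_reference",
    "pair_sessions",
]

#: Default geometry pairing tolerances: 0.1 mm positions, 0.5 deg angles.
POSITION_TOL_CM = 0.01
ANGLE_TOL_DEG = 0.5


class GeometryMismatchError(ValueError):
    """Raised when a PSD/dummy pair was not acquired at the same geometry."""


def _geometry_close(
    a: DosePoint | float,
    b: DosePoint | float,
    pos_tol: float = POSITION_TOL_CM,
    ang_tol: float = ANGLE_TOL_DEG,
) -> bool:
    if isinstance(a, DosePoint) and isinstance(b, DosePoint):
        return math.hypot(a.y - b.y, a.z - b.z) <= pos_tol
    if isinstance(a, DosePoint) or isinstance(b, DosePoint):
        return False
    return abs(float(a) - float(b)) <= ang_tol


@dataclass(frozen=True)
class Acquisition:
    """One acquisition of a probe.

    ``rate`` is the detected count rate per 100 ms; ``duration`` the
    exposure in seconds; ``geometry`` either a :class:`DosePoint` (cm) or
    an angle in degrees.  Unless repeated acquisitions say otherwise, the
    Type A relative uncertainty is Poisson: 1/sqrt(total counts).
    """

    rate: float
    duration: float
    timestamp: datetime
    geometry: DosePoint | float
    probe_kind: Literal["psd", "dummy"] = "psd"
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("count rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.probe_kind not in ("psd", "dummy"):
            raise ValueError(f"unknown probe_kind {self.probe_kind!r}")

    @property
    def counts(self) -> float:
        """Total counts accumulated over the exposure."""
        return self.rate * self.duration / 0.1

    @property
    def u_rel(self) -> float:
        """Poisson Type A relative uncertainty (k=1); inf for zero counts."""
        n = self.counts
        return 1.0 / math.sqrt(n) if n > 0 else math.inf


@dataclass(frozen=True)
class CorrectedSignal:
    """A stem-corrected (and possibly decay-normalized) net count rate."""

    net_rate: float
    u_rel: float
    geometry: DosePoint | float
    timestamp: datetime | None = None
    temperature: float | None = None
    negative_flag: bool = False

    def __post_init__(self) -> None:
        if self.u_rel < 0:
            raise ValueError("u_rel must be >= 0")


@dataclass
class MeasurementSession:
    """An ordered set of acquisitions from one probe."""

    acquisitions: list[Acquisition] = field(default_factory=list)
    probe_kind: Literal["psd", "dummy"] = "psd"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.acquisitions:
            if a.probe_kind != self.probe_kind:
                raise ValueError(
                    f"acquisition probe_kind {a.probe_kind!r} does not match "
                    f"session probe_kind {self.probe_kind!r}"
                )

    def __len__(self) -> int:
        return len(self.acquisitions)

    def __iter__(self):
        return iter(self.acquisitions)

    # -- JSON I/O (ISO-8601 timestamps) -----------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def enc(a: Acquisition) -> dict:
            if isinstance(a.geometry, DosePoint):
                geom = {"y_cm": a.geometry.y, "z_cm": a.geometry.z}
            else:
                geom = {"angle_deg": float(a.geometry)}
            rec = {
                "rate_per_100ms": a.rate,
                "duration_s": a.duration,
                "timestamp": a.timestamp.isoformat(),
                "geometry": geom,
                "probe_kind": a.probe_kind,
            }
            if a.temperature is not None:
                rec["temperature_c"] = a.temperature
            return rec

        payload = {
            "probe_kind": self.probe_kind,
            "metadata": self.metadata,
            "acquisitions": [enc(a) for a in self.acquisitions],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MeasurementSession":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        raw = json.loads(text)
        acqs = []
        for rec in raw["acquisitions"]:
            g = rec["geometry"]
            geometry: DosePoint | float
            if "angle_deg" in g:
                geometry = float(g["angle_deg"])
            else:
                geometry = DosePoint(y=float(g["y_cm"]), z=float(g["z_cm"]))
            acqs.append(
                Acquisition(
                    rate=float(rec["rate_per_100ms"]),
                    duration=float(rec["duration_s"]),
                    timestamp=datetime.fromisoformat(rec["timestamp"]),
                    geometry=geometry,
                    probe_kind=rec.get("probe_kind", raw.get("probe_kind", "psd")),
                    temperature=rec.get("temperature_c"),
                )
            )
        return cls(
            acquisitions=acqs,
            probe_kind=raw.get("probe_kind", "psd"),
            metadata=raw.get("metadata", {}),
        )


def subtract_stem(
    psd: Acquisition,
    dummy: Acquisition,
    pos_tol: float = POSITION_TOL_CM,
    ang_tol: float = ANGLE_TOL_DEG,
) -> CorrectedSignal:
    """Net scintillation rate: PSD rate minus the paired dummy (stem) rate.

    The Type A uncertainties of both acquisitions combine in quadrature.
    Negative net rates are retained — clamping would bias means of
    repeated low-signal measurements — but flagged when more than three
    standard deviations below zero.
    """
    if not _geometry_close(psd.geometry, dummy.geometry, pos_tol, ang_tol):
        raise GeometryMismatchError(
            f"PSD geometry {psd.geometry} and dummy geometry {dummy.geometry} "
            "were not acquired at the same position"
        )
    net = psd.rate - dummy.rate
    u_abs = math.hypot(
        psd.rate * (0.0 if math.isinf(psd.u_rel) else psd.u_rel),
        dummy.rate * (0.0 if math.isinf(dummy.u_rel) else dummy.u_rel),
    )
    u_rel = abs(u_abs / net) if net != 0 else math.inf
    flag = bool(net < 0 and u_abs > 0 and net < -3.0 * u_abs)
    return CorrectedSignal(
        net_rate=net,
        u_rel=u_rel,
        geometry=psd.geometry,
        timestamp=psd.timestamp,
        temperature=psd.temperature,
        negative_flag=flag,
    )


def pair_sessions(
    psd: MeasurementSession,
    dummy: MeasurementSession,
    pos_tol: float = POSITION_TOL_CM,
    ang_tol: float = ANGLE_TOL_DEG,
) -> list[CorrectedSignal]:
    """Stem-correct a PSD session against a dummy session acquired over the
    same geometries, pairing acquisitions by geometry."""
    remaining = list(dummy.acquisitions)
    out = []
    for a in psd.acquisitions:
        match = next(
            (d for d in remaining if _geometry_close(a.geometry, d.geometry, pos_tol, ang_tol)),
            None,
        )
        if match is None:
            raise GeometryMismatchError(
                f"no dummy acquisition matches PSD geometry {a.geometry}"
            )
        remaining.remove(match)
        out.append(subtract_stem(a, match, pos_tol, ang_tol))
    return out


def decay_normalize(
    signals: Sequence[CorrectedSignal],
    source: SourceState,
    ref_time: datetime | None = None,
    threshold: float = 0.002,
) -> list[CorrectedSignal]:
    """Remove source decay: divide each net rate by RAKR(t)/RAKR(ref).

    When the maximum decay variation across the session is below
    ``threshold`` (default 0.2%, relative) the correction is skipped and
    the signals are returned unchanged — short sessions on a long-lived
    source do not warrant it.
    """
    if ref_time is None:
        ref_time = source.ref_time
    rakr_ref = decay_correct(source, ref_time)
    factors = []
    for s in signals:
        if s.timestamp is None:
            raise ValueError("decay normalization requires timestamps")
        factors.append(decay_correct(source, s.timestamp) / rakr_ref)
    if factors and max(abs(f - 1.0) for f in factors) < threshold:
        return list(signals)
    return [replace(s, net_rate=s.net_rate / f) for s, f in zip(signals, factors)]


def normalize_to_reference(
    signals: Sequence[CorrectedSignal],
    reference: AwayAlongTable,
    point: DosePoint,
    sk: float = 1.0,
    pos_tol: float = POSITION_TOL_CM,
) -> tuple[list[CorrectedSignal], float]:
    """Anchor a measured grid to a reference dose-rate table.

    The grid is rescaled so its value at ``point`` equals the reference
    dose rate there; returns the rescaled signals and the scale factor
    (reference dose rate per unit measured rate).
    """
    anchor = next(
        (
            s
            for s in signals
            if isinstance(s.geometry, DosePoint)
            and _geometry_close(s.geometry, point, pos_tol)
        ),
        None,
    )
    if anchor is None:
        raise ValueError(f"no measured signal at the normalization point {point}")
    if anchor.net_rate <= 0:
        raise ValueError("net rate at the normalization point must be > 0")
    scale = dose_rate_at(reference, point, sk) / anchor.net_rate
    return [replace(s, net_rate=s.net_rate * scale) for s in signals], scale
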
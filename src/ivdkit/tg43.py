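"""Reference dose engine for an Ir-192 HDR source.

Handles the away-along dose-rate table (2D tabulation of absorbed dose
rate to water per unit air-kerma strength around a cylindrically
symmetric source), the TG-43 line-source geometry function, source decay
correction and positional-sensitivity estimates.

Coordinate convention
---------------------
``z`` runs along the source axis, positive toward the drive cable;
``y`` is the perpendicular ("away") distance.  The polar angle ``theta``
is measured from the +z axis.  Table axes are in centimetres; helper
converters are provided for the millimetre quantities that appear at
API boundaries (source steps, displacements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "IR192_HALF_LIFE_DAYS",
    "SourceState",
    "AwayAlongTable",
    "DosePoint",
    "TableFormatError",
    "OutOfRangeError",
    "load_away_along",
    "dose_rate_at",
    "geometry_function_line",
    "decay_correct",
    "displacement_sensitivity",
    "mm_to_cm",
    "cm_to_mm",
    "sk_from_rakr",
]

#: Ir-192 half-life in days (standard reference value).
IR192_HALF_LIFE_DAYS = 73.83

#: CSV corner label marking rows = along (z), columns = away (y).
_CORNER = "z\\y"


class TableFormatError(ValueError):
    """Raised when an away-along CSV grid is malformed."""


class OutOfRangeError(ValueError):
    """Raised when a query point lies outside the tabulated grid."""


def mm_to_cm(x: float) -> float:
    return x / 10.0


def cm_to_mm(x: float) -> float:
    return x * 10.0


def sk_from_rakr(rakr_mgy_m2_h: float) -> float:
    """Air-kerma strength in U (uGy.m2/h) from an RAKR in mGy.m2/h."""
    return rakr_mgy_m2_h * 1000.0


@dataclass
class SourceState:
    """Strength and decay state of an HDR source.

    Parameters
    ----------
    rakr : float
        Reference air-kerma rate in mGy.m2/h at ``ref_time``.
    ref_time : datetime
        Timestamp the RAKR refers to.
    half_life : float
        Radioactive half-life in days.
    active_length : float
        Active source length in mm; 0 means a point source.
    """

    rakr: float
    ref_time: datetime
    half_life: float = IR192_HALF_LIFE_DAYS
    active_length: float = 0.0

    def __post_init__(self) -> None:
        if self.rakr <= 0:
            raise ValueError(f"rakr must be > 0, got {self.rakr}")
        if self.half_life <= 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")
        if self.active_length < 0:
            raise ValueError("active_length must be >= 0")

    @property
    def sk(self) -> float:
        """Air-kerma strength in U at the reference time."""
        return sk_from_rakr(self.rakr)

    def rakr_at(self, t: datetime) -> float:
        return decay_correct(self, t)


@dataclass(frozen=True)
class DosePoint:
    """A query point in source coordinates: away ``y`` and along ``z``, cm."""

    y: float
    z: float

    def __post_init__(self) -> None:
        if self.y == 0.0 and self.z == 0.0:
            raise ValueError("(y, z) = (0, 0) coincides with the source")

    @property
    def r(self) -> float:
        """Radial distance from the source centre, cm."""
        return math.hypot(self.y, self.z)

    @property
    def theta(self) -> float:
        """Polar angle from the +z source axis, degrees."""
        return math.degrees(math.atan2(self.y, self.z))


@dataclass
class AwayAlongTable:
    """Absorbed dose rate to water per unit air-kerma strength on a
    rectangular (away, along) grid.

    ``values[i, j]`` is the rate in cGy/(h.U) at ``along[i]``, ``away[j]``.
    """

    away: np.ndarray
    along: np.ndarray
    values: np.ndarray
    _interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.away = np.asarray(self.away, dtype=float)
        self.along = np.asarray(self.along, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.away.ndim != 1 or self.along.ndim != 1:
            raise TableFormatError("axes must be one-dimensional")
        if np.any(np.diff(self.away) <= 0):
            raise TableFormatError("away axis must be strictly increasing")
        if np.any(np.diff(self.along) <= 0):
            raise TableFormatError("along axis must be strictly increasing")
        if self.values.shape != (self.along.size, self.away.size):
            raise TableFormatError(
                f"values shape {self.values.shape} does not match "
                f"(n_along, n_away) = ({self.along.size}, {self.away.size})"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableFormatError(
                f"non-finite value at along={self.along[i]}, away={self.away[j]}"
            )
        pos = self.away > 0
        if np.any(self.values[:, pos] <= 0):
            raise TableFormatError("dose-rate values must be > 0 for y > 0")

    # -- interpolation ----------------------------------------------------
    def _interpolator(self) -> RegularGridInterpolator:
        # Bilinear on r^2-flattened values: the inverse-square gradient is
        # divided out before interpolating and restored at the query point,
        # which keeps the steep near-source falloff from biasing the
        # interpolant.
        if self._interp is None:
            zz, yy = np.meshgrid(self.along, self.away, indexing="ij")
            r2 = yy**2 + zz**2
            self._interp = RegularGridInterpolator(
                (self.along, self.away),
                self.values * r2,
                method="linear",
                bounds_error=True,
            )
        return self._interp

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "AwayAlongTable":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise TableFormatError(f"cannot parse {path}: {exc}") from exc
        try:
            away = df.columns.to_numpy(dtype=float)
            along = df.index.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"{path}: axis labels must be numeric distances"
            ) from exc
        values = df.to_numpy(dtype=float)
        if np.any(pd.isna(values)):
            i, j = np.argwhere(pd.isna(values))[0]
            raise TableFormatError(
                f"{path}: missing cell at along={along[i]}, away={away[j]}"
            )
        return cls(away=away, along=along, values=values)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.along, columns=self.away)
        df.index.name = _CORNER
        df.to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.along, columns=self.away)
        df.index.name = _CORNER
        return df


def load_away_along(path: str | Path) -> AwayAlongTable:
    """Read an away-along table from CSV.

    Layout: first cell ``z\\y``, header row of away distances (cm), first
    column of along distances (cm), body of dose rates in cGy/(h.U).
    """
    return AwayAlongTable.from_csv(path)


def dose_rate_at(table: AwayAlongTable, p: DosePoint, sk: float = 1.0) -> float:
    """Dose rate in cGy/h at ``p`` for a source of air-kerma strength ``sk`` (U).

    Grid nodes are reproduced exactly; between nodes the table is
    interpolated bilinearly after multiplying the stored values by r^2,
    and the interpolant is divided by r^2 at the query point.  Queries
    outside the grid raise :class:`OutOfRangeError` (no extrapolation).
    """
    if sk <= 0:
        raise ValueError("air-kerma strength must be > 0")
    try:
        flat = float(table._interpolator()([[p.z, p.y]])[0])
    except ValueError as exc:
        raise OutOfRangeError(
            f"point (y={p.y}, z={p.z}) lies outside the tabulated grid "
            f"y in [{table.away[0]}, {table.away[-1]}], "
            f"z in [{table.along[0]}, {table.along[-1]}]"
        ) from exc
    return sk * flat / (p.r**2)


def geometry_function_line(r: float, theta: float, L: float) -> float:
    """TG-43 line-source geometry function G_L(r, theta) in cm^-2.

    Parameters
    ----------
    r : float
        Distance from the source centre, cm (> 0).
    theta : float
        Polar angle from the source axis, degrees.
    L : float
        Active length, cm.  ``L = 0`` gives the point-source limit 1/r^2.

    Notes
    -----
    For an off-axis point G_L = beta / (L r sin(theta)), with beta the
    angle subtended by the active line at the point.  On the axis the
    limit 1/(r^2 - L^2/4) is used.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if L < 0:
        raise ValueError("L must be >= 0")
    if L == 0.0:
        return 1.0 / r**2
    th = math.radians(theta)
    y = r * math.sin(th)
    z = r * math.cos(th)
    if abs(y) < 1e-12 * r:
        if r <= L / 2:
            raise ValueError("on-axis point inside the active length")
        return 1.0 / (r**2 - L**2 / 4.0)
    y = abs(y)
    beta = math.atan2(L / 2.0 - z, y) + math.atan2(L / 2.0 + z, y)
    return beta / (L * r * math.sin(th))


def decay_correct(source: SourceState, t: datetime) -> float:
    """RAKR at time ``t``: rakr * 2**(-dt / half_life), dt in days."""
    dt_days = (t - source.ref_time) / timedelta(days=1)
    return source.rakr * 2.0 ** (-dt_days / source.half_life)


def displacement_sensitivity(d_perp: float, delta_long: float) -> float:
    """Percent signal change from a longitudinal source displacement.

    Inverse-square model: a detector at perpendicular distance ``d_perp``
    (mm) sees the source move by ``delta_long`` (mm) along the catheter;
    the relative signal change is ``100 * (1 - d^2 / (d^2 + delta^2))``.
    """
    if d_perp <= 0:
        raise ValueError("d_perp must be > 0")
    d2 = d_perp**2
    return 100.0 * (1.0 - d2 / (d2 + delta_long**2))
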
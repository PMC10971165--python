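"""GUM-style measurement-uncertainty engine.

Type A components come from the repeatability of a set of measurements;
Type B components from certificates or assumed distributions.  All
relative components are expressed in percent at k=1 and combined in
quadrature; a coverage factor k expands the combined value to the
desired confidence level.

Temperature during an irradiation set is known only before and after
(``t_initial``, ``t_final``); treating the true value as uniformly
distributed over that interval gives a standard uncertainty of the
interval amplitude divided by sqrt(12), combined in quadrature with the
thermometer calibration uncertainty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "TemperatureReading",
    "type_a",
    "uniform_interval_u",
    "combine_quadrature",
    "expand",
    "temperature_signal_uncertainty",
    "round_half_up",
    "load_budget",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (budget display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class UncertaintyComponent:
    """A named relative uncertainty component, percent at k=1."""

    name: str
    kind: Literal["A", "B"]
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("A", "B"):
            raise ValueError(f"kind must be 'A' or 'B', got {self.kind!r}")
        if self.value < 0:
            raise ValueError("component value must be >= 0")


@dataclass
class UncertaintyBudget:
    """A list of components whose quadrature combination is recomputed on
    every access, so the budget can never go stale."""

    components: list[UncertaintyComponent] = field(default_factory=list)

    @property
    def combined(self) -> float:
        """Combined relative uncertainty, percent at k=1."""
        return combine_quadrature([c.value for c in self.components])

    def add(self, name: str, kind: Literal["A", "B"], value: float) -> None:
        self.components.append(UncertaintyComponent(name, kind, value))

    def to_markdown(self, decimals: int = 1) -> str:
        lines = [
            "| Uncertainty component | Type A [%] | Type B [%] |",
            "|---|---|---|",
        ]
        for c in self.components:
            a = f"{round_half_up(c.value, decimals):.{decimals}f}" if c.kind == "A" else "-"
            b = f"{round_half_up(c.value, decimals):.{decimals}f}" if c.kind == "B" else "-"
            lines.append(f"| {c.name} | {a} | {b} |")
        total = round_half_up(self.combined, decimals)
        lines.append(f"| Total combined uncertainty (k=1) | {total:.{decimals}f}% | |")
        return "\n".join(lines)

    def to_csv(self, path: str | Path, decimals: int = 1) -> None:
        import pandas as pd

        rows = [
            {
                "component": c.name,
                "type": c.kind,
                "u_rel_pct": round_half_up(c.value, decimals),
            }
            for c in self.components
        ]
        rows.append(
            {
                "component": "Total combined (k=1)",
                "type": "",
                "u_rel_pct": round_half_up(self.combined, decimals),
            }
        )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class TemperatureReading:
    """Water temperature before and after an irradiation set, with the
    thermometer calibration uncertainty (degC, k=1)."""

    t_initial: float
    t_final: float
    u_cal: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_initial) and math.isfinite(self.t_final)):
            raise ValueError("temperatures must be finite")
        if self.u_cal < 0:
            raise ValueError("u_cal must be >= 0")

    @property
    def mean(self) -> float:
        return 0.5 * (self.t_initial + self.t_final)


def type_a(values: Sequence[float], of_mean: bool = False) -> float:
    """Type A relative uncertainty in percent: 100 * SD / mean.

    At least three repeats are required.  ``of_mean=True`` divides the SD
    by sqrt(n) (standard deviation of the mean) instead of reporting the
    spread of the set.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"need >= 3 repeated measurements, got {v.size}")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean of the measurements is zero")
    sd = v.std(ddof=1)
    if of_mean:
        sd /= math.sqrt(v.size)
    return 100.0 * sd / abs(mean)


def uniform_interval_u(r: TemperatureReading) -> float:
    """Standard uncertainty (degC, k=1) of a temperature known only at the
    start and end of an irradiation: |interval| / sqrt(12), in quadrature
    with the calibration uncertainty."""
    u_interval = abs(r.t_initial - r.t_final) / math.sqrt(12.0)
    return math.hypot(u_interval, r.u_cal)


def combine_quadrature(components: Iterable[float]) -> float:
    """Quadratic sum sqrt(sum u_i^2) of non-negative components."""
    comp = list(components)
    if any(u < 0 for u in comp):
        raise ValueError("components must be >= 0")
    return math.sqrt(sum(u * u for u in comp))


def expand(u: float, k: float) -> float:
    """Expanded uncertainty k * u."""
    if k <= 0:
        raise ValueError("coverage factor k must be > 0")
    return k * u


def temperature_signal_uncertainty(u_temp_expanded: float, model) -> float:
    """Relative signal uncertainty in percent induced by a temperature
    uncertainty through the linear temperature coefficient of the
    detector: |a| * u_T * 100."""
    return abs(model.a) * u_temp_expanded * 100.0


def load_budget(name_or_path: str | Path) -> UncertaintyBudget:
    """Load a budget from a bundled fixture name (``"mc"``, ``"farmer"``)
    or a JSON file path."""
    if name_or_path in ("mc", "farmer"):
        text = (
            resources.files("ivdkit")
            .joinpath(f"data/budget_{name_or_path}.json")
            .read_text()
        )
    else:
        text = Path(name_or_path).read_text()
    raw = json.loads(text)
    comps = [
        UncertaintyComponent(c["name"], c["kind"], float(c["value"]))
        for c in raw["components"]
    ]
    return UncertaintyBudget(components=comps)
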
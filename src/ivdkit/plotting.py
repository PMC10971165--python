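"""Plot helpers: angular radar diagrams and temperature-fit panels."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .characterization import AngularSweep, TemperatureModel, relative_response

__all__ = ["plot_angular_radar", "plot_temperature_fit"]


def plot_angular_radar(
    sweeps: Sequence[AngularSweep],
    labels: Sequence[str] | None = None,
    path: str | Path | None = None,
):
    """Radar (polar) diagram of one or more angular sweeps."""
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for i, sweep in enumerate(sweeps):
        theta = np.radians(np.r_[sweep.angles, sweep.angles[0]])
        rates = np.r_[sweep.net_rates, sweep.net_rates[0]]
        label = labels[i] if labels else f"{sweep.plane} @ {sweep.radius:g} mm"
        ax.plot(theta, rates, marker="o", ms=3, label=label)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=8)
    ax.set_title("Angular response (count rate per 100 ms)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_temperature_fit(
    temps: Sequence[float],
    signals: Sequence[float],
    model: TemperatureModel,
    path: str | Path | None = None,
):
    """Normalized response vs temperature with the fitted line."""
    temps = np.asarray(temps, float)
    signals = np.asarray(signals, float)
    fig, ax = plt.subplots()
    ax.plot(temps, signals / model.s0, "o", ms=4, label="measured / S0")
    grid = np.linspace(temps.min(), temps.max(), 50)
    ax.plot(grid, [relative_response(model, t) for t in grid], "-",
            label=f"fit: a = {model.a:.4f} /degC")
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel(f"S(T) / S({model.t0:g} degC)")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
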
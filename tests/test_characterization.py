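"""Energy/angular-dependence summaries and the temperature model."""

import math
import random

import numpy as np
import pytest

from ivdkit import (
    AngularSweep,
    CorrectedSignal,
    DosePoint,
    FitError,
    GeneratorConfig,
    TemperatureModel,
    angular_summary,
    away_along_comparison,
    dose_rate_at,
    fit_temperature_model,
    relative_response,
    simulate_temperature_session,
    temperature_correction,
)
from tests.conftest import EPOCH


def _grid_signals(table, factor=lambda p: 1.0):
    sigs = []
    for z in table.along:
        for y in table.away:
            p = DosePoint(y=float(y), z=float(z))
            v = dose_rate_at(table, p, 1.0) * factor(p)
            sigs.append(CorrectedSignal(net_rate=v, u_rel=0.0, geometry=p, timestamp=EPOCH))
    return sigs


# -- away-along comparison ------------------------------------------------


def test_identical_grids_give_zero_stats(toy_table):
    stats = away_along_comparison(_grid_signals(toy_table), toy_table)
    assert stats.mean_pct == pytest.approx(0.0, abs=1e-10)
    assert stats.sd_pct == pytest.approx(0.0, abs=1e-10)
    assert stats.max_abs_pct == pytest.approx(0.0, abs=1e-10)
    assert stats.z0_mean_pct == pytest.approx(0.0, abs=1e-10)


def test_uniform_two_percent_offset(toy_table):
    anchor = DosePoint(y=4.0, z=0.0)
    stats = away_along_comparison(
        _grid_signals(toy_table, lambda p: 1.0 if p == anchor else 1.02), toy_table
    )
    non_anchor = [pct for g, pct in stats.per_point if g != anchor]
    assert np.mean(non_anchor) == pytest.approx(2.0, rel=1e-9)
    assert stats.max_abs_pct == pytest.approx(2.0, rel=1e-9)


def test_stats_invariant_to_traversal_order(toy_table):
    sigs = _grid_signals(toy_table, lambda p: 1.0 + 0.01 * p.y)
    shuffled = sigs.copy()
    random.Random(7).shuffle(shuffled)
    a = away_along_comparison(sigs, toy_table)
    b = away_along_comparison(shuffled, toy_table)
    assert a.mean_pct == pytest.approx(b.mean_pct, rel=1e-12)
    assert a.sd_pct == pytest.approx(b.sd_pct, rel=1e-12)
    assert a.per_away_max == pytest.approx(b.per_away_max)


def test_injected_radial_profile_recovered_per_point(toy_table):
    eps = lambda r: 1.0 + 0.002 * (r - 4.0)
    stats = away_along_comparison(
        _grid_signals(toy_table, lambda p: eps(p.r)), toy_table
    )
    for g, pct in stats.per_point:
        assert pct == pytest.approx(100.0 * (eps(g.r) - 1.0), abs=1e-9)
    # per-radius maxima of |pct| follow the profile magnitude at the
    # grid's z extremes
    for y, mx in stats.per_away_max.items():
        r_max = math.hypot(y, 7.0)
        assert mx == pytest.approx(abs(100.0 * (eps(r_max) - 1.0)), abs=1e-9)


# -- angular summary ------------------------------------------------------


def test_flat_sweep_gives_zero():
    sweep = AngularSweep(
        plane="axial",
        angles=np.arange(30.0, 331.0, 20.0),
        net_rates=np.full(16, 500.0),
        radius=60.0,
    )
    stats = angular_summary(sweep)
    assert stats.mean_pct == 0.0
    assert stats.sd_pct == 0.0


def test_hand_computed_deviations_about_mean():
    sweep = AngularSweep(
        plane="axial",
        angles=np.array([30.0, 50.0, 70.0, 90.0]),
        net_rates=np.array([100.0, 100.0, 102.0, 98.0]),
        radius=60.0,
    )
    stats = angular_summary(sweep)
    assert stats.mean_pct == pytest.approx(1.0)
    signed = dict(stats.per_point)
    assert signed[70.0] == pytest.approx(2.0)
    assert signed[90.0] == pytest.approx(-2.0)


def test_sweep_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        AngularSweep(plane="axial", angles=[90.0, 30.0], net_rates=[1.0, 2.0], radius=60)
    with pytest.raises(ValueError, match="plane"):
        AngularSweep(plane="radial", angles=[30.0, 50.0], net_rates=[1.0, 2.0], radius=60)


# -- temperature model ----------------------------------------------------


def test_noiseless_linear_data_recovered_exactly():
    a, s0, t0 = -0.0019, 1000.0, 25.0
    temps = np.array([15.0, 20.0, 25.0, 30.0, 35.0, 40.0])
    signals = s0 * (1.0 + a * (temps - t0))
    model = fit_temperature_model(temps, signals, t0=t0)
    assert model.a == pytest.approx(a, abs=1e-12)
    assert model.s0 == pytest.approx(s0, rel=1e-12)
    assert model.u_a == pytest.approx(0.0, abs=1e-12)


def test_constant_signal_gives_zero_slope():
    model = fit_temperature_model([15.0, 25.0, 35.0], [800.0, 800.0, 800.0])
    assert model.a == 0.0


def test_fit_requires_three_distinct_temperatures():
    with pytest.raises(FitError):
        fit_temperature_model([20.0, 20.0, 30.0, 30.0], [1.0, 1.0, 2.0, 2.0])


def test_fit_is_shift_equivariant():
    rng = np.random.default_rng(3)
    temps = np.repeat([15.0, 20.0, 25.0, 30.0, 35.0, 40.0], 5)
    signals = 1000.0 * (1.0 - 0.0019 * (temps - 25.0)) * (1 + rng.normal(0, 0.003, temps.size))
    m1 = fit_temperature_model(temps, signals, t0=25.0)
    m2 = fit_temperature_model(temps + 7.0, signals, t0=32.0)
    assert m2.a == pytest.approx(m1.a, rel=1e-12)


def test_temperature_uncertainty_adds_type_b_term():
    rng = np.random.default_rng(5)
    temps = np.repeat([15.0, 20.0, 25.0, 30.0, 35.0, 40.0], 5)
    signals = 1000.0 * (1.0 - 0.0019 * (temps - 25.0)) * (1 + rng.normal(0, 0.003, temps.size))
    bare = fit_temperature_model(temps, signals)
    with_b = fit_temperature_model(temps, signals, u_temps=0.3)
    assert with_b.u_a > bare.u_a
    assert with_b.a == bare.a


def test_slope_recovery_at_stated_noise():
    # Compact simulation oracle; the 200-session version runs in the
    # acceptance suite.
    a_true = -0.0019
    for seed in range(25):
        cfg = GeneratorConfig(seed=seed, noise_model="gaussian", gaussian_pct=0.3)
        session, _ = simulate_temperature_session(cfg)
        model = fit_temperature_model(
            [acq.temperature for acq in session], [acq.rate for acq in session]
        )
        assert abs(model.a - a_true) <= 2e-4


# -- temperature correction -----------------------------------------------


def test_correction_identities():
    model = TemperatureModel(a=-0.0019, t0=25.0, s0=1000.0, fitted_range=(15.0, 40.0))
    assert temperature_correction(model, 25.0) == 1.0
    for t in (15.0, 31.0, 40.0):
        assert temperature_correction(model, t) * relative_response(model, t) == pytest.approx(
            1.0, rel=1e-15
        )


def test_body_temperature_response_drop():
    model = TemperatureModel(a=-0.0019, t0=25.0, s0=1.0)
    rel = relative_response(model, 37.0)
    assert 100.0 * (rel - 1.0) == pytest.approx(-2.28, abs=1e-12)
    assert temperature_correction(model, 37.0) == pytest.approx(1.0 / 0.9772, rel=1e-12)


def test_extrapolation_warns_and_degenerate_raises():
    model = TemperatureModel(a=-0.0019, t0=25.0, s0=1.0, fitted_range=(15.0, 40.0))
    with pytest.warns(UserWarning, match="outside the fitted range"):
        temperature_correction(model, 60.0)
    steep = TemperatureModel(a=-0.04, t0=25.0, s0=1.0)
    with pytest.raises(ValueError, match="invalid"):
        temperature_correction(steep, 60.0)
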
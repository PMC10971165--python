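"""Reference dose engine: table I/O, interpolation, geometry function,
decay and positional sensitivity."""

import math
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ivdkit import (
    AwayAlongTable,
    DosePoint,
    OutOfRangeError,
    SourceState,
    TableFormatError,
    decay_correct,
    displacement_sensitivity,
    dose_rate_at,
    geometry_function_line,
    load_away_along,
)
from tests.conftest import EPOCH


# -- table I/O ------------------------------------------------------------


def test_csv_round_trip_is_identity(toy_table, tmp_path):
    path = tmp_path / "table.csv"
    toy_table.to_csv(path)
    back = load_away_along(path)
    np.testing.assert_allclose(back.away, toy_table.away)
    np.testing.assert_allclose(back.along, toy_table.along)
    np.testing.assert_allclose(back.values, toy_table.values, rtol=1e-12)


def test_missing_cell_is_a_parse_error_naming_the_location(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("z\\y,1.0,2.0\n-1.0,0.5,0.3\n0.0,1.0,\n1.0,0.5,0.3\n")
    with pytest.raises(TableFormatError, match="along=0.0"):
        load_away_along(path)


@pytest.mark.parametrize(
    "away, along",
    [([2.0, 1.0, 3.0], [-1.0, 0.0, 1.0]), ([1.0, 2.0, 3.0], [0.0, 0.0, 1.0])],
)
def test_non_monotone_axis_rejected(away, along):
    with pytest.raises(TableFormatError, match="strictly increasing"):
        AwayAlongTable(away=away, along=along, values=np.ones((3, 3)))


def test_shape_mismatch_rejected():
    with pytest.raises(TableFormatError, match="shape"):
        AwayAlongTable(away=[1.0, 2.0], along=[0.0, 1.0], values=np.ones((3, 2)))


# -- interpolation --------------------------------------------------------


def test_grid_nodes_reproduced_exactly(toy_table):
    for i, z in enumerate(toy_table.along):
        for j, y in enumerate(toy_table.away):
            got = dose_rate_at(toy_table, DosePoint(y=float(y), z=float(z)), sk=1.0)
            assert got == pytest.approx(toy_table.values[i, j], rel=1e-12)


def test_node_query_scales_linearly_with_sk(toy_table):
    p = DosePoint(y=4.0, z=0.0)
    one = dose_rate_at(toy_table, p, sk=1.0)
    assert dose_rate_at(toy_table, p, sk=38300.0) == pytest.approx(38300.0 * one, rel=1e-12)


@given(
    y=st.floats(1.0, 6.0),
    z=st.floats(-7.0, 7.0),
)
@settings(max_examples=200, deadline=None)
def test_interpolated_field_matches_inverse_square_everywhere(
    inverse_square_table, y, z
):
    # The r^2-flattened interpolant represents a 1/r^2 field exactly, so
    # any in-hull query must return the closed form.
    got = dose_rate_at(inverse_square_table, DosePoint(y=y, z=z), sk=1.0)
    expected = 1.109 / (y * y + z * z)
    assert got == pytest.approx(expected, rel=1e-9)


def test_midpoint_lies_between_flattened_corner_bounds(toy_table):
    # Brute-force bound: the interpolant at a cell midpoint must sit
    # between the min and max of the four surrounding r^2-flattened
    # values divided by r^2 at the query point.
    y, z = 2.5, 1.5
    got = dose_rate_at(toy_table, DosePoint(y=y, z=z), sk=1.0)
    corners = []
    for zi in (1.0, 2.0):
        for yi in (2.0, 3.0):
            i = list(toy_table.along).index(zi)
            j = list(toy_table.away).index(yi)
            corners.append(toy_table.values[i, j] * (yi**2 + zi**2))
    r2 = y * y + z * z
    assert min(corners) / r2 <= got <= max(corners) / r2


def test_query_outside_grid_raises(toy_table):
    with pytest.raises(OutOfRangeError):
        dose_rate_at(toy_table, DosePoint(y=0.5, z=0.0), sk=1.0)
    with pytest.raises(OutOfRangeError):
        dose_rate_at(toy_table, DosePoint(y=4.0, z=7.5), sk=1.0)


# -- geometry function ----------------------------------------------------


def _line_oracle(r, theta_deg, L):
    """Quadrature oracle: average inverse-square distance to the active
    line, (1/L) * integral dl / |P - (0, l)|^2."""
    th = math.radians(theta_deg)
    y, z = r * math.sin(th), r * math.cos(th)
    val, _ = quad(lambda l: 1.0 / (y**2 + (z - l) ** 2), -L / 2, L / 2)
    return val / L


def test_point_source_limit():
    assert geometry_function_line(2.0, 37.0, 0.0) == pytest.approx(0.25)


@pytest.mark.parametrize("r,theta", [(1.0, 90.0), (1.0, 30.0), (2.0, 120.0)])
def test_line_source_matches_quadrature_oracle(r, theta):
    L = 0.35
    got = geometry_function_line(r, theta, L)
    assert got == pytest.approx(_line_oracle(r, theta, L), rel=1e-6)


def test_far_field_approaches_inverse_square():
    got = geometry_function_line(100.0, 90.0, 0.35)
    assert got == pytest.approx(1e-4, rel=1e-5)


def test_converges_monotonically_to_point_source_as_length_shrinks():
    r = 2.0
    values = [geometry_function_line(r, 90.0, L) for L in (0.8, 0.4, 0.2, 0.1, 0.0)]
    # On the transverse axis G_L < 1/r^2 and increases toward it as L -> 0.
    assert all(a < b for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(1.0 / r**2)


def test_on_axis_limit_and_domain_errors():
    L = 0.35
    assert geometry_function_line(2.0, 0.0, L) == pytest.approx(
        1.0 / (4.0 - L**2 / 4.0)
    )
    with pytest.raises(ValueError):
        geometry_function_line(0.0, 90.0, L)
    with pytest.raises(ValueError):
        geometry_function_line(0.1, 0.0, L)  # on-axis inside active length


# -- decay ----------------------------------------------------------------


def test_decay_closed_forms(source):
    assert decay_correct(source, EPOCH) == pytest.approx(38.3)
    one_half_life = EPOCH + timedelta(days=source.half_life)
    assert decay_correct(source, one_half_life) == pytest.approx(38.3 / 2)
    t = EPOCH + timedelta(days=7.383)
    assert decay_correct(source, t) == pytest.approx(38.3 * 2 ** (-0.1), rel=1e-12)


@given(dt1=st.floats(-50, 50), dt2=st.floats(-50, 50))
@settings(max_examples=100, deadline=None)
def test_decay_is_multiplicative_over_intervals(source, dt1, dt2):
    t1 = EPOCH + timedelta(days=dt1)
    mid = SourceState(
        rakr=decay_correct(source, t1), ref_time=t1, half_life=source.half_life
    )
    t2 = t1 + timedelta(days=dt2)
    assert decay_correct(mid, t2) == pytest.approx(
        decay_correct(source, t2), rel=1e-12
    )


# -- positional sensitivity -----------------------------------------------


def test_displacement_examples():
    assert displacement_sensitivity(60.0, 0.0) == 0.0
    assert displacement_sensitivity(60.0, 1.0) == pytest.approx(
        100.0 * (1.0 - 3600.0 / 3601.0), rel=1e-12
    )
    assert displacement_sensitivity(10.0, 1.0) == pytest.approx(
        100.0 * (1.0 - 100.0 / 101.0), rel=1e-12
    )


@given(
    d=st.floats(1.0, 200.0),
    delta=st.one_of(st.floats(0.01, 5.0), st.floats(-5.0, -0.01)),
)
@settings(max_examples=100, deadline=None)
def test_displacement_even_in_delta_and_decreasing_in_distance(d, delta):
    s = displacement_sensitivity(d, delta)
    assert s == pytest.approx(displacement_sensitivity(d, -delta), rel=1e-12)
    assert displacement_sensitivity(d + 1.0, delta) < s


def test_displacement_requires_positive_distance():
    with pytest.raises(ValueError):
        displacement_sensitivity(0.0, 1.0)
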
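"""Lead-trajectory geometry: point formula, d1/d2 statistics, frame changes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vimtarget.geometry import (
    ContactGeometry,
    DegenerateTrajectoryError,
    Frame,
    FrameMismatchError,
    FrameOrigin,
    LeadTrajectory,
    MEDTRONIC_3389,
    StereotacticAccuracy,
    accuracy_d1,
    accuracy_d2,
    bipolar_midpoint,
    contact_centers,
    convert_frame,
    point_on_lead,
    unit_direction,
)


@pytest.mark.parametrize(
    "a, j, expected",
    [
        ((0, 0, 0), (0, 0, 10), (0, 0, 1)),
        ((0, 0, 0), (3, 0, 4), (0.6, 0, 0.8)),
        ((1, -2, 5), (1, -2, 4), (0, 0, -1)),
    ],
)
def test_unit_direction_points_from_tip_to_proximal(a, j, expected):
    u = unit_direction(a, j)
    np.testing.assert_allclose(u, expected, atol=1e-12)
    assert abs(np.linalg.norm(u) - 1.0) < 1e-9


def test_unit_direction_rejects_coincident_points():
    with pytest.raises(DegenerateTrajectoryError):
        unit_direction((1, 1, 1), (1, 1, 1))


@pytest.mark.parametrize(
    "a, u, d, expected",
    [
        ((10, 5, -2), (0, 0, 1), 0, (10, 5, -2)),
        ((10, 5, -2), (0, 0, 1), 3, (10, 5, 1)),
        ((0, 0, 0), (0.6, 0, 0.8), 5, (3, 0, 4)),
    ],
)
def test_point_on_lead_formula(a, u, d, expected):
    m = point_on_lead(a, u, d)
    np.testing.assert_allclose(m, expected, atol=1e-12)
    assert abs(np.linalg.norm(m - np.asarray(a, float)) - d) < 1e-9


def test_point_on_lead_requires_unit_direction():
    with pytest.raises(ValueError):
        point_on_lead((0, 0, 0), (0, 0, 2.0), 1.0)


def test_point_on_lead_recovers_proximal_point(rng):
    for _ in range(20):
        a, j = rng.normal(size=3), rng.normal(size=3)
        u = unit_direction(a, j)
        m = point_on_lead(a, u, float(np.linalg.norm(j - a)))
        np.testing.assert_allclose(m, j, atol=1e-9)


def test_contact_centers_spacing_rule():
    traj = LeadTrajectory(tip_A=(0, 0, 0), proximal_J=(0, 0, 10))
    geom = ContactGeometry(n_contacts=4, contact_length=1.5, inter_contact_gap=0.5,
                           tip_to_first_contact_center=1.5)
    centers = contact_centers(traj, geom)
    assert len(centers) == 4
    np.testing.assert_allclose([c[2] for c in centers], [1.5, 3.5, 5.5, 7.5])
    # constant pitch between consecutive centers, any direction
    traj2 = LeadTrajectory(tip_A=(1, 2, 3), proximal_J=(4, 8, 9))
    centers2 = contact_centers(traj2, geom)
    gaps = [np.linalg.norm(c2 - c1) for c1, c2 in zip(centers2, centers2[1:])]
    np.testing.assert_allclose(gaps, 2.0, atol=1e-9)


def test_single_contact_lead():
    traj = LeadTrajectory(tip_A=(0, 0, 0), proximal_J=(0, 0, 10))
    geom = ContactGeometry(n_contacts=1, tip_to_first_contact_center=2.25)
    (center,) = contact_centers(traj, geom)
    np.testing.assert_allclose(center, (0, 0, 2.25))


def test_medtronic_3389_dimensions():
    assert MEDTRONIC_3389.diameter == pytest.approx(1.28)
    assert MEDTRONIC_3389.contact_length == pytest.approx(1.5)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0, 0, 0), (2, 2, 2), (1, 1, 1)),
        ((1, 0, 0), (0, 1, 0), (0.5, 0.5, 0)),
        ((3, -1, 2), (3, -1, 2), (3, -1, 2)),
    ],
)
def test_bipolar_midpoint(a, b, expected):
    np.testing.assert_allclose(bipolar_midpoint(a, b), expected)


def test_accuracy_d1_examples(rng):
    assert accuracy_d1((1, 2, 3), (1, 2, 3)) == 0.0
    assert accuracy_d1((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
    for _ in range(50):
        m, t = rng.normal(size=3), rng.normal(size=3)
        assert accuracy_d1(m, t) == pytest.approx(np.sqrt(np.sum((m - t) ** 2)))
        assert accuracy_d1(m, t) == pytest.approx(accuracy_d1(t, m))


def test_accuracy_d2_examples():
    assert accuracy_d2((0, 0, 0), (0, 0, 1), (3, 4, 7)) == pytest.approx(5.0)
    # a point on the axis has zero distance
    assert accuracy_d2((1, 1, 1), (0, 1, 0), (1, 7.5, 1)) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DegenerateTrajectoryError):
        accuracy_d2((0, 0, 0), (0, 0, 0), (1, 1, 1))


def test_d2_invariant_to_sliding_along_axis(rng):
    for _ in range(50):
        L, T = rng.normal(size=3), rng.normal(size=3)
        u = rng.normal(size=3)
        d_ref = accuracy_d2(L, u, T)
        s = rng.normal() * 10
        shifted = L + s * u
        assert accuracy_d2(shifted, u, T) == pytest.approx(d_ref, abs=1e-9)


def test_d2_never_exceeds_d1_of_any_axis_point(rng):
    for _ in range(50):
        L, T = rng.normal(size=3), rng.normal(size=3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        d2 = accuracy_d2(L, u, T)
        for s in rng.normal(size=10) * 5:
            assert d2 <= accuracy_d1(point_on_lead(L, u, 0) + s * u, T) + 1e-9


def test_stereotactic_accuracy_invariant():
    StereotacticAccuracy(d1=2.0, d2=1.5)
    with pytest.raises(ValueError):
        StereotacticAccuracy(d1=1.0, d2=1.5)


def test_convert_frame_mcp_to_pc():
    src = Frame(FrameOrigin.MCP, 24.0)
    dst = Frame(FrameOrigin.PC, 24.0)
    # the classical surgical target x=13, y=-4, z=0 at MCP is y=8 at PC
    np.testing.assert_allclose(convert_frame((13, -4, 0), src, dst), (13, 8, 0))


def test_convert_frame_round_trip_and_identity(rng):
    pc, mcp = Frame(FrameOrigin.PC, 27.5), Frame(FrameOrigin.MCP, 27.5)
    p = rng.normal(size=3) * 10
    np.testing.assert_allclose(convert_frame(p, pc, pc), p)
    back = convert_frame(convert_frame(p, pc, mcp), mcp, pc)
    np.testing.assert_allclose(back, p, atol=1e-12)


def test_convert_frame_rejects_mismatched_acpc():
    with pytest.raises(FrameMismatchError):
        convert_frame((0, 0, 0), Frame(FrameOrigin.PC, 24.0), Frame(FrameOrigin.MCP, 26.0))


# ---------------------------------------------------------------------------
# property tests

coord = st.floats(min_value=-50.0, max_value=50.0, allow_nan=False)
point = st.tuples(coord, coord, coord)


@settings(derandomize=True, max_examples=100)
@given(a=point, j=point)
def test_unit_direction_norm_and_orientation_property(a, j):
    a, j = np.array(a), np.array(j)
    if np.linalg.norm(j - a) < 1e-6:
        return
    u = unit_direction(a, j)
    assert abs(np.linalg.norm(u) - 1.0) < 1e-9
    # u points from A toward J: positive projection onto (J - A)
    assert np.dot(u, j - a) > 0


@settings(derandomize=True, max_examples=100)
@given(L=point, direction=point, T=point, s=st.floats(-20, 20))
def test_d2_lower_bounds_d1_property(L, direction, T, s):
    L, u, T = np.array(L), np.array(direction), np.array(T)
    if np.linalg.norm(u) < 1e-6:
        return
    un = u / np.linalg.norm(u)
    d2 = accuracy_d2(L, u, T)
    assert d2 <= accuracy_d1(L + s * un, T) + 1e-9
    # and sliding the anchor along the axis leaves d2 unchanged
    assert accuracy_d2(L + s * un, u, T) == pytest.approx(d2, abs=1e-8)


@settings(derandomize=True, max_examples=100)
@given(p=point, acpc=st.floats(min_value=20.0, max_value=32.0))
def test_frame_round_trip_property(p, acpc):
    pc, mcp = Frame(FrameOrigin.PC, acpc), Frame(FrameOrigin.MCP, acpc)
    there = convert_frame(p, pc, mcp)
    back = convert_frame(there, mcp, pc)
    np.testing.assert_allclose(back, np.asarray(p), atol=1e-12)
    assert there[0] == p[0] and there[2] == p[2]
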
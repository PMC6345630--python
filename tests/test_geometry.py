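"""Contour -> axis -> radius profile -> area/volume measurements."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rodsizer import (
    CellContour,
    CellGeometry,
    RadiusProfile,
    compute_symmetry_axis,
    geometry_by_rotation,
    geometry_spherocylinder,
    make_contour,
    measure_contour,
    population_mean_radius,
    radius_profile,
)
from rodsizer.geometry import (
    AxisUndefinedError,
    geometry_frame,
    measure_contours,
    read_contour_csv,
    spherocylinder_area,
    spherocylinder_volume,
    write_geometry_csv,
)


def spherocylinder_profile(L, R, n=801):
    """Exact analytic profile used as the rotation-method oracle."""
    x = np.linspace(0.0, L, n)
    left = np.clip(2 * R * x - x**2, 0.0, None)
    right = np.clip(2 * R * (L - x) - (L - x) ** 2, 0.0, None)
    r = np.where(x < R, np.sqrt(left), np.where(x > L - R, np.sqrt(right), R))
    return RadiusProfile(x=x, r=r, L=L)


class TestClosedForms:
    @pytest.mark.parametrize(
        "L, R, A, V",
        [
            # A = 2*pi*1.876*14 matches the division area of normal-width
            # cells; V = pi*1.876^2*(17.53 - 2*1.876/3) matches the division
            # volume when area sensing is lost.
            (14.0, 1.876, 165.03, 140.96),
            (17.53, 1.876, 206.64, 180.00),
        ],
    )
    def test_printed_division_geometry(self, L, R, A, V):
        a, v = geometry_spherocylinder(L, R)
        assert a == pytest.approx(A, abs=0.01)
        assert v == pytest.approx(V, abs=0.01)

    def test_sphere_limit_allowed(self):
        A, V = geometry_spherocylinder(4.0, 2.0)
        assert A == pytest.approx(4 * math.pi * 4)
        assert V == pytest.approx(4 / 3 * math.pi * 8)

    def test_not_a_rod(self):
        with pytest.raises(ValueError, match="not a rod"):
            geometry_spherocylinder(3.0, 2.0)

    @given(
        L=st.floats(5.0, 30.0),
        R=st.floats(0.5, 2.5),
        dL=st.floats(0.1, 5.0),
        dR=st.floats(0.01, 0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_area_linear_volume_monotone(self, L, R, dL, dR):
        # A = 2*pi*R*L is exactly linear in each argument; V increases in both
        assert spherocylinder_area(L + dL, R) == pytest.approx(
            spherocylinder_area(L, R) + 2 * math.pi * R * dL
        )
        if L > 2 * (R + dR):
            assert spherocylinder_volume(L + dL, R) > spherocylinder_volume(L, R)
            assert spherocylinder_volume(L, R + dR) > spherocylinder_volume(L, R)


class TestRotation:
    @pytest.mark.parametrize("L, R", [(14.0, 2.0), (8.0, 1.5), (25.0, 2.2), (5.0, 2.4)])
    def test_rotation_matches_closed_form(self, L, R):
        A, V = geometry_by_rotation(spherocylinder_profile(L, R))
        A0, V0 = geometry_spherocylinder(L, R)
        assert A == pytest.approx(A0, rel=0.005)
        assert V == pytest.approx(V0, rel=0.005)

    def test_hemisphere_pair_is_sphere(self):
        A, _ = geometry_by_rotation(spherocylinder_profile(4.0, 2.0))
        assert A == pytest.approx(4 * math.pi * 4, rel=0.005)

    def test_capless_cylinder_volume(self):
        x = np.linspace(2.0, 12.0, 201)
        prof = RadiusProfile(x=x - 2.0, r=np.full_like(x, 2.0), L=10.0)
        _, V = geometry_by_rotation(prof)
        assert V == pytest.approx(math.pi * 4 * 10, rel=0.005)

    def test_too_few_samples(self):
        prof = RadiusProfile(x=np.linspace(0, 10, 5), r=np.ones(5), L=10.0)
        with pytest.raises(ValueError):
            geometry_by_rotation(prof)


class TestAxis:
    def test_axis_aligned(self, ideal_contour):
        axis = compute_symmetry_axis(ideal_contour)
        assert abs(axis.direction @ np.array([1.0, 0.0])) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("deg", [30.0, -45.0, 120.0])
    def test_rotated_contour(self, ideal_contour, deg):
        th = math.radians(deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        rotated = CellContour(ideal_contour.vertices @ rot.T, "rot")
        axis = compute_symmetry_axis(rotated)
        expected = rot @ np.array([1.0, 0.0])
        angle = math.degrees(math.acos(min(abs(axis.direction @ expected), 1.0)))
        assert angle < 1.0

    def test_circle_is_degenerate(self):
        th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        circle = CellContour(np.column_stack([np.cos(th), np.sin(th)]), "circle")
        with pytest.raises(AxisUndefinedError):
            compute_symmetry_axis(circle)


class TestRadiusProfile:
    def test_ideal_spherocylinder(self, ideal_contour):
        prof = radius_profile(ideal_contour)
        assert prof.L == pytest.approx(14.0, rel=0.01)
        mid = (prof.x > 3.0) & (prof.x < 11.0)
        assert np.allclose(prof.r[mid], 2.0, atol=0.05)
        # profile pinned to zero at the poles
        assert prof.r[0] == 0.0 and prof.r[-1] == 0.0

    def test_noisy_contour_mean_radius(self):
        """Vertex jitter of 0.05 um averages out over 100 seeds."""
        mids = []
        for seed in range(100):
            c = make_contour(14.0, 2.0, n_vertices=64, jitter_sd=0.05, seed=seed)
            prof = radius_profile(c)
            mid = (prof.x > 3.0) & (prof.x < prof.L - 3.0)
            mids.append(prof.r[mid].mean())
        assert np.mean(mids) == pytest.approx(2.0, abs=0.02)

    @given(
        th=st.floats(0.0, 2 * math.pi),
        tx=st.floats(-50.0, 50.0),
        ty=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, th, tx, ty):
        base = make_contour(12.0, 1.8, n_vertices=128)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = CellContour(base.vertices @ rot.T + np.array([tx, ty]), "m")
        g0 = measure_contour(base)
        g1 = measure_contour(moved)
        assert g1.L == pytest.approx(g0.L, rel=0.005)
        assert g1.A_rot == pytest.approx(g0.A_rot, rel=0.005)
        assert g1.V_rot == pytest.approx(g0.V_rot, rel=0.005)


class TestPopulationRadius:
    def test_mean_of_radii(self):
        cells = [CellGeometry.from_length_radius(14.0, r) for r in (1.8, 2.0, 2.2)]
        R_bar, out = population_mean_radius(cells)
        assert R_bar == pytest.approx(2.0)
        assert all(c.methodology == 3 for c in out)
        assert out[0].A_sc == pytest.approx(spherocylinder_area(14.0, 2.0))

    def test_single_cell_identity(self):
        cell = CellGeometry.from_length_radius(14.0, 1.9)
        _, (out,) = population_mean_radius([cell])
        assert out.A_sc == pytest.approx(cell.A_sc)
        assert out.V_sc == pytest.approx(cell.V_sc)

    def test_empty_population(self):
        with pytest.raises(ValueError):
            population_mean_radius([])

    def test_methodologies_agree_at_small_radius_noise(self):
        """3% radius CV: population-radius areas track single-cell areas to <1%."""
        rng = np.random.default_rng(0)
        cells = [
            CellGeometry.from_length_radius(14.0, 1.876 * (1 + 0.03 * rng.standard_normal()))
            for _ in range(1000)
        ]
        _, pop = population_mean_radius(cells)
        m2 = np.mean([c.A_sc for c in cells])
        m3 = np.mean([c.A_sc for c in pop])
        assert abs(m3 - m2) / m2 < 0.01

    def test_identical_on_constant_radius(self):
        """All three methodologies coincide for a noise-free population."""
        contours = [make_contour(L, 2.0, n_vertices=512, cell_id=f"c{L}") for L in (10.0, 14.0)]
        cells = [measure_contour(c) for c in contours]
        _, pop = population_mean_radius(cells)
        for c2, c3 in zip(cells, pop):
            assert c3.A_sc == pytest.approx(c2.A_sc, rel=0.01)
            assert c2.A_rot == pytest.approx(c2.A_sc, rel=0.01)


def test_contour_csv_roundtrip(tmp_path):
    import pandas as pd

    contours = [make_contour(14.0, 2.0, cell_id="a"), make_contour(10.0, 1.5, cell_id="b")]
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append({"cell_id": c.cell_id, "vertex_index": i, "x_um": x, "y_um": y})
    path = tmp_path / "contours.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    back = read_contour_csv(path)
    assert [c.cell_id for c in back] == ["a", "b"]
    np.testing.assert_allclose(back[0].vertices, contours[0].vertices)

    cells = measure_contours(back, methodology=3)
    out = tmp_path / "geom.csv"
    write_geometry_csv(cells, out)
    df = pd.read_csv(out)
    assert set(df.columns) >= {"cell_id", "L", "R_mean", "A_sc", "V_sc", "methodology"}
    assert (df["methodology"] == 3).all()
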
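"""Germ measurements, growth curves, screens, stress maps, tracking and
the geometric elongation model."""

import numpy as np
import pytest

from toothmorph.cells import GrowthConfig
from toothmorph.experiments import (
    MeasurementError,
    RunConfig,
    contact_stress_map,
    curve_error,
    geometric_elongation,
    measure_growth_angle,
    measure_growth_curves,
    measure_loop_lengths,
    parameter_screen,
    run_simulation,
    track_cells,
)
from toothmorph.state import MESENCHYME, SUPRABASAL, StateBuilder
from toothmorph.synthetic import ReferenceCurves


def knot_with_tips(tip_left, tip_right):
    """Minimal 2D state: a knot cell at the origin plus two epithelial
    cells whose basal nodes sit at the prescribed tip positions."""
    b = StateBuilder(2)
    b.add_epithelial(apical=[0, 1.0], basal=[0, 0.0], knot=True)
    for tip in (tip_left, tip_right):
        tip = np.asarray(tip, float)
        b.add_epithelial(apical=tip + [0, 1.0], basal=tip)
    return b.build()


class TestGrowthAngle:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ((-1.0, 0.0), (1.0, 0.0), 180.0),   # tips level with the knot
            ((-1.0, -1.0), (1.0, -1.0), 90.0),  # dot-product arithmetic
            ((-0.1, -2.0), (0.1, -2.0), np.degrees(2 * np.arctan(0.1 / 2.0))),
        ],
    )
    def test_reference_geometries(self, left, right, expected):
        state = knot_with_tips(left, right)
        assert measure_growth_angle(state) == pytest.approx(expected, abs=1e-9)

    def test_missing_side_flagged(self):
        b = StateBuilder(2)
        b.add_epithelial(apical=[0, 1], basal=[0, 0], knot=True)
        b.add_epithelial(apical=[1, 1], basal=[1, 0])
        with pytest.raises(MeasurementError):
            measure_growth_angle(b.build())

    def test_no_knot_flagged(self):
        b = StateBuilder(2)
        b.add_epithelial(apical=[0, 1], basal=[0, 0])
        with pytest.raises(MeasurementError):
            measure_growth_angle(b.build())


class TestLoopLengths:
    def test_2d_state_rejected(self):
        with pytest.raises(MeasurementError):
            measure_loop_lengths(knot_with_tips((-1, -1), (1, -1)))

    def test_flat_bud_depth(self):
        """A square skirt of epithelium around a knot: every quadrant
        reads the same prescribed depth below the fixed border."""
        b = StateBuilder(3)
        b.add_epithelial(apical=[0, 0, -1.0], basal=[0, 0, -2.0], knot=True)
        for x, y in [(2, 0), (-2, 0), (0, 2), (0, -2)]:
            b.add_epithelial(apical=[x, y, -2.0], basal=[x, y, -3.0])
        for x, y in [(4, 0), (-4, 0), (0, 4), (0, -4)]:
            b.add_epithelial(apical=[x, y, 1.0], basal=[x, y, 0.0], fixed=True)
        state = b.build()
        lengths = measure_loop_lengths(state)
        assert all(v == pytest.approx(3.0) for v in lengths.values())


def square_state(side=1.0, n_extra=0):
    b = StateBuilder(2)
    for x, y in [(0, 0), (side, 0), (side, side), (0, side)]:
        b.add_sphere([x, y], SUPRABASAL)
    return b.build()


class TestGrowthCurves:
    def test_unit_square_area(self):
        """Triangulated unit square of suprabasal nodes has area 1."""
        curves = measure_growth_curves([square_state()], reference_unit=1.0)
        assert curves.area[0] == pytest.approx(1.0)

    def test_static_snapshots_constant(self):
        snaps = [square_state() for _ in range(4)]
        for i, s in enumerate(snaps):
            s.time = float(i)
        curves = measure_growth_curves(snaps, reference_unit=1.0)
        assert np.allclose(curves.area, curves.area[0])

    def test_similarity_scaling(self):
        """Scaling all coordinates x2 doubles perimeter, quadruples area."""
        b = StateBuilder(2)
        for k in range(6):
            b.add_epithelial(apical=[0.8 * k, 1.0], basal=[0.8 * k, 0.0])
        for x in np.arange(0.4, 4.2, 0.8):
            for y in (1.8, 2.6):
                b.add_sphere([x, y], SUPRABASAL)
        s1 = b.build()
        s2 = s1.copy()
        s2.positions = 2.0 * s2.positions
        s2.p_ADD = 2.0 * s2.p_ADD  # keep contacts intact under scaling
        s2.p_EQD = 2.0 * s2.p_EQD
        c1 = measure_growth_curves([s1], reference_unit=1.0)
        c2 = measure_growth_curves([s2], reference_unit=1.0)
        assert c2.perimeter[0] == pytest.approx(2 * c1.perimeter[0], rel=1e-9)
        assert c2.area[0] == pytest.approx(4 * c1.area[0], rel=1e-9)


class TestCurveError:
    def grid(self, *values):
        t = np.linspace(0, 100, len(values[0]))
        return ReferenceCurves(t, np.asarray(values[0], float),
                               np.asarray(values[1], float))

    def test_identical_zero(self):
        a = self.grid([1, 2, 3, 4], [1, 1.5, 2, 2.5])
        assert curve_error(a, a) == 0.0

    def test_constant_offset_contribution(self):
        """A constant offset delta on one unit-mean curve contributes
        exactly delta to the pooled RMSE."""
        n = 50
        ones = np.ones(n)
        a = self.grid(ones, ones)
        b = self.grid(ones + 0.25, ones)
        assert curve_error(a, b, normalize=False) == pytest.approx(0.25)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = self.grid(rng.uniform(1, 2, 20), rng.uniform(1, 2, 20))
        b = self.grid(rng.uniform(1, 2, 20), rng.uniform(1, 2, 20))
        assert curve_error(a, b) == pytest.approx(curve_error(b, a))

    def test_scale_invariance_with_normalization(self):
        """Unit normalization makes the error blind to per-curve units."""
        a = self.grid([1, 2, 3, 4.0], [1, 1.2, 1.5, 2.0])
        b = self.grid([10, 20, 30, 40.0], [3, 3.6, 4.5, 6.0])
        assert curve_error(a, b) == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def tiny_bud():
    from toothmorph.synthetic import BudGeometry, build_bud_2d

    g = BudGeometry(AP_halflength=6.0, BL_halflength=6.0, bud_depth=2.5,
                    mesenchyme_depth=1.5, suprabasal_layers=1, knot_width=3)
    return build_bud_2d(g, relax_max_steps=300, seed=0)


class TestRunSimulation:

    def test_zero_growth_is_fixed_point(self, tiny_bud):
        cfg = RunConfig(
            growth=GrowthConfig(hypothesis="I", s_epi=0, s_sup=0, s_mes=0),
            total_time=2.0, seed=0)
        snaps = run_simulation(tiny_bud, cfg)
        drift = np.abs(snaps[-1].positions - snaps[0].positions).max()
        assert snaps[-1].n_cells == snaps[0].n_cells
        assert drift < 0.5  # residual settling only, no growth-driven motion

    def test_same_seed_identical_streams(self, tiny_bud):
        cfg = RunConfig(
            growth=GrowthConfig(hypothesis="I", s_epi=0.3, s_sup=0.05,
                                s_mes=0.05),
            total_time=3.0, seed=42, snapshot_interval=1.0)
        a = run_simulation(tiny_bud, cfg)
        b = run_simulation(tiny_bud, cfg)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)

    def test_runaway_growth_aborts(self, tiny_bud):
        cfg = RunConfig(
            growth=GrowthConfig(hypothesis="I", s_epi=2.0, s_sup=2.0, s_mes=2.0),
            total_time=5.0, seed=0, max_cells=300)
        with pytest.raises(RuntimeError, match="runaway"):
            run_simulation(tiny_bud, cfg)

    def test_screen_row_count_and_seeds(self, tiny_bud):
        cfg = RunConfig(
            growth=GrowthConfig(hypothesis="I", s_epi=0.1, s_sup=0.05,
                                s_mes=0.05),
            total_time=1.0, seed=100)
        table = parameter_screen(tiny_bud, {"b_MM": [0.5, 1.0],
                                            "s_epi": [0.1, 0.2]}, cfg)
        assert len(table) == 4
        assert sorted(table["seed"]) == [100, 101, 102, 103]

    def test_unknown_screen_parameter_rejected(self, tiny_bud):
        cfg = RunConfig(growth=GrowthConfig(), total_time=1.0, seed=0)
        with pytest.raises(ValueError):
            parameter_screen(tiny_bud, {"b_XX": [1.0]}, cfg)


class TestTracking:
    def test_trajectories_are_bookkeeping(self):
        """Scripted linear motion: trajectories equal the script."""
        b = StateBuilder(2)
        b.add_sphere([0, 0], MESENCHYME)
        b.add_sphere([5, 0], MESENCHYME)
        base = b.build()
        snaps = []
        for t in range(4):
            s = base.copy()
            s.positions = base.positions + np.array([0.1, 0.2]) * t
            s.time = float(t)
            snaps.append(s)
        traj = track_cells(snaps, np.array([0, 1]))
        assert traj.shape == (4, 2, 2)
        for t in range(4):
            assert np.allclose(traj[t] - traj[0], np.array([0.1, 0.2]) * t)

    def test_missing_cell_rejected(self):
        b = StateBuilder(2)
        b.add_sphere([0, 0], MESENCHYME)
        state = b.build()
        with pytest.raises(ValueError):
            track_cells([state], np.array([5]))


class TestStressMap:
    def test_sign_convention(self):
        """Stretched adhesive bond positive, compressed contact negative,
        rest distance zero."""
        for d, sign in [(1.0, 0), (1.2, +1), (0.8, -1)]:
            b = StateBuilder(2)
            b.add_sphere([0, 0], MESENCHYME)
            b.add_sphere([d, 0], MESENCHYME)
            edges, _ = contact_stress_map(b.build())
            assert len(edges) == 1
            assert np.sign(edges["stress"].iloc[0]) == sign

    def test_epithelial_cell_average(self):
        b = StateBuilder(2)
        b.add_epithelial(apical=[0, 0.5], basal=[0, -0.5])
        b.add_sphere([0.8, -0.5], MESENCHYME)
        edges, per_cell = contact_stress_map(b.build())
        assert (per_cell["cell_id"] == 0).all()
        incident = edges["stress"]
        assert per_cell["mean_stress"].iloc[0] == pytest.approx(incident.mean())


class TestGeometricElongation:
    def test_exponent_ratio_is_half(self):
        res = geometric_elongation(0.7)
        assert res.exponent_ratio == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_growth(self):
        res = geometric_elongation(0.5, r_bl0=2.0, duration=3.0)
        assert np.allclose(res.r_bl / 2.0, np.exp(0.5 * res.time), rtol=1e-12)

    def test_zero_rate_constant(self):
        res = geometric_elongation(0.0)
        assert np.allclose(res.r_ap, res.r_ap[0])
        assert np.allclose(res.r_bl, res.r_bl[0])
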
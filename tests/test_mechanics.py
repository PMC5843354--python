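"""Force-law oracles and integrator contracts."""

import numpy as np
import pytest

from toothmorph import mechanics as mech
from toothmorph.state import (
    MESENCHYME,
    SUPRABASAL,
    AdhesionTable,
    NodeState,
    StateBuilder,
)

from conftest import random_node


def make_node(pos, p_REC=1.0, p_EQD=0.5, p_ADD=0.7, expr=(1, 0, 0), **kw):
    return NodeState(id=0, position=np.asarray(pos, float), p_REC=p_REC,
                     p_EQD=p_EQD, p_ADD=p_ADD, expression=np.asarray(expr, float),
                     **kw)


class TestPairForce:
    @pytest.mark.parametrize(
        "d, b_EE, expected",
        [
            (1.0, 5.0, 0.0),     # both branches vanish at the rest distance
            (0.8, 5.0, -0.4),    # repulsive branch: 2.0 * (0.8 - 1.0)
            (1.2, 5.0, 1.0),     # adhesive branch: k_ADH=5, 5 * 0.2
            (1.5, 5.0, 0.0),     # beyond the cut-off: contact lost
            (1.4, 5.0, 2.0),     # at the cut-off the adhesive branch still acts
        ],
    )
    def test_hand_values(self, d, b_EE, expected):
        a = make_node([0, 0, 0])
        b = make_node([d, 0, 0])
        adh = AdhesionTable.from_pairs(b_EE=b_EE)
        assert mech.pair_interaction_force(a, b, adh) == pytest.approx(expected)

    def test_cutoff_discontinuity(self):
        """The adhesive branch drops from k_ADH*(ADDsum-EQDsum) to zero."""
        adh = AdhesionTable.from_pairs(b_EE=5.0)
        a = make_node([0, 0, 0])
        just_in = mech.pair_interaction_force(a, make_node([1.4, 0, 0]), adh)
        just_out = mech.pair_interaction_force(a, make_node([1.4 + 1e-9, 0, 0]), adh)
        assert just_in == pytest.approx(5.0 * 0.4)
        assert just_out == 0.0

    def test_adhesion_strength_double_sum(self):
        """k_ADH sums g_im g_jn b_mn over all molecule pairs."""
        rng = np.random.default_rng(0)
        gi, gj = rng.uniform(0, 2, 3), rng.uniform(0, 2, 3)
        b = rng.uniform(0, 3, (3, 3))
        b = 0.5 * (b + b.T)
        expected = sum(gi[m] * gj[n] * b[m, n] for m in range(3) for n in range(3))
        got = mech.adhesion_strength(gi, gj, AdhesionTable(b))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_node([0, 0, 0], p_REC=-1.0)
        with pytest.raises(ValueError):
            AdhesionTable.from_pairs(b_EE=-0.5)


class TestSpringForce:
    def test_rest_length_zero(self):
        ap = make_node([0, 0, 0], p_HOO=0.5)
        ba = make_node([0, 0, -1.0], p_HOO=0.5)
        fa, fb = mech.epithelial_spring_force(1.0, ap, ba)
        assert np.allclose(fa, 0) and np.allclose(fb, 0)

    @pytest.mark.parametrize("d, sign", [(1.3, -1), (0.7, +1)])
    def test_stretch_and_compression(self, d, sign):
        """|f| = (p_HOO sum)(d - EQS) = 0.3, contracting when stretched."""
        ap = make_node([0, 0, 0], p_HOO=0.5)
        ba = make_node([0, 0, -d], p_HOO=0.5)
        fa, fb = mech.epithelial_spring_force(1.0, ap, ba)
        assert np.allclose(fa, -fb)
        assert np.linalg.norm(fa) == pytest.approx(0.3)
        # stretched: apical pulled towards basal (-z); compressed: pushed away (+z)
        assert np.sign(fa[2]) == sign

    def test_zero_length_cylinder_rejected(self):
        ap = make_node([0, 0, 0])
        ba = make_node([0, 0, 0])
        with pytest.raises(ValueError):
            mech.epithelial_spring_force(1.0, ap, ba)


class TestBendingForces:
    def test_right_angles_give_zero(self):
        i = make_node([0, 0, 0])
        j = make_node([1, 0, 0])
        f_est, f_erp = mech.epithelial_bending_forces(i, j, [0, 0, 1], [0, 0, 1])
        assert np.allclose(f_est, 0) and np.allclose(f_erp, 0)

    def test_radial_hand_value(self):
        i = make_node([0, 0, 0], p_EST=0.5)
        j = make_node([1, 0, 0.2], p_EST=0.5)
        f_est, _ = mech.epithelial_bending_forces(i, j, [0, 0, 1], [0, 0, 1])
        assert np.allclose(f_est, [0, 0, 0.2], atol=1e-12)

    def test_rotational_hand_value(self):
        i = make_node([0, 0, 0], p_ERP=1.0)
        j = make_node([1, 0, 0.2])
        _, f_erp = mech.epithelial_bending_forces(i, j, [0, 0, 1], [0, 0, 1])
        expected = 0.2 * np.array([1, 0, 0.2]) / np.sqrt(1.04)
        assert np.allclose(f_erp, expected, atol=1e-12)

    def test_antiparallel_axes_zero_radial(self):
        i = make_node([0, 0, 0])
        j = make_node([1, 0, 0])
        f_est, _ = mech.epithelial_bending_forces(i, j, [0, 0, 1], [0, 0, -1])
        assert np.allclose(f_est, 0)


class TestNeighborGraph:
    @pytest.mark.parametrize("d, n_edges", [(1.5, 0), (1.3, 1), (1.4, 1)])
    def test_cutoff(self, d, n_edges):
        b = StateBuilder(3)
        b.add_sphere([0, 0, 0], MESENCHYME)
        b.add_sphere([d, 0, 0], MESENCHYME)
        graph = mech.build_neighbor_graph(b.build())
        assert graph.n_edges == n_edges

    def test_matches_brute_force_on_random_cloud(self):
        """KD-tree edge set equals the O(n^2) all-pairs oracle."""
        rng = np.random.default_rng(42)
        b = StateBuilder(3)
        pts = rng.uniform(0, 6, (150, 3))
        for p in pts:
            b.add_sphere(p, MESENCHYME)
        state = b.build()
        # vary the interaction radii so the pairwise cut-off is exercised
        state.p_ADD = rng.uniform(0.4, 0.9, 150)
        graph = mech.build_neighbor_graph(state)
        got = {tuple(sorted(p)) for p in graph.pairs.tolist()}
        expected = set()
        for i in range(150):
            for j in range(i + 1, 150):
                if np.linalg.norm(pts[i] - pts[j]) <= state.p_ADD[i] + state.p_ADD[j]:
                    expected.add((i, j))
        assert got == expected

    def test_coincident_nodes_get_unit_vector(self):
        b = StateBuilder(3)
        b.add_sphere([1, 1, 1], MESENCHYME)
        b.add_sphere([1, 1, 1], MESENCHYME)
        graph = mech.build_neighbor_graph(b.build())
        assert graph.n_edges == 1
        assert np.linalg.norm(graph.unit[0]) == pytest.approx(1.0)


class TestTotalForces:
    def test_isolated_node_zero(self):
        b = StateBuilder(3)
        b.add_sphere([0, 0, 0], MESENCHYME)
        state = b.build()
        fld = mech.total_forces(state, mech.build_neighbor_graph(state))
        assert np.allclose(fld.forces, 0)

    def test_action_reaction_sums_to_zero(self):
        """Pairwise and spring contributions cancel over a closed system."""
        rng = np.random.default_rng(7)
        b = StateBuilder(3)
        for p in rng.uniform(0, 4, (40, 3)):
            b.add_sphere(p, MESENCHYME if rng.random() < 0.5 else SUPRABASAL)
        state = b.build()
        state.p_EST = np.zeros(40)  # no epithelium: all terms are pairwise
        fld = mech.total_forces(state, mech.build_neighbor_graph(state))
        assert np.allclose(fld.forces.sum(axis=0), 0, atol=1e-12)

    def test_three_node_system_matches_scalar_oracle(self):
        """Aggregated field equals the per-term scalar evaluation."""
        b = StateBuilder(3)
        b.add_sphere([0, 0, 0], MESENCHYME)
        b.add_sphere([1.2, 0, 0], MESENCHYME)
        b.add_sphere([0.5, 0.8, 0], SUPRABASAL)
        state = b.build()
        fld = mech.total_forces(state, mech.build_neighbor_graph(state))
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                ni, nj = state.node(i), state.node(j)
                f = mech.pair_interaction_force(ni, nj, state.adhesion)
                d = nj.position - ni.position
                if np.linalg.norm(d) <= ni.p_ADD + nj.p_ADD:
                    expected[i] += f * d / np.linalg.norm(d)
        assert np.allclose(fld.forces, expected, atol=1e-12)

    def test_fixed_nodes_masked(self, two_spheres):
        two_spheres.fixed[0] = True
        fld = mech.total_forces(two_spheres,
                                mech.build_neighbor_graph(two_spheres))
        assert np.allclose(fld.forces[0], 0)
        assert not np.allclose(fld.forces[1], 0)

    def test_scalar_law_on_random_draws(self):
        """1000 random parameter draws: the scalar contact law equals an
        inline branch-by-branch evaluation to 1e-12."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            a = random_node(rng)
            c = random_node(rng)
            expected = mech.pair_interaction_force(a, c, AdhesionTable())
            d = np.linalg.norm(c.position - a.position)
            eqd = a.p_EQD + c.p_EQD
            add = a.p_ADD + c.p_ADD
            if d < eqd:
                manual = (a.p_REC + c.p_REC) * (d - eqd)
            elif d <= add:
                manual = float(a.expression @ np.ones((3, 3)) @ c.expression) * (d - eqd)
            else:
                manual = 0.0
            assert expected == pytest.approx(manual, abs=1e-12)


class TestFlatSheetFixedPoint:
    def test_chain_2d(self, flat_sheet_2d):
        fld = mech.total_forces(flat_sheet_2d,
                                mech.build_neighbor_graph(flat_sheet_2d))
        assert np.abs(fld.forces).max() < 1e-9

    def test_sheet_3d(self, flat_sheet_3d):
        fld = mech.total_forces(flat_sheet_3d,
                                mech.build_neighbor_graph(flat_sheet_3d))
        assert np.abs(fld.forces).max() < 1e-9


class TestIntegration:
    def test_zero_force_leaves_positions(self, flat_sheet_2d):
        before = flat_sheet_2d.positions.copy()
        mech.integrate_step(flat_sheet_2d, 0.1)
        assert np.allclose(flat_sheet_2d.positions, before)

    def test_dt_validation(self, two_spheres):
        with pytest.raises(ValueError):
            mech.integrate_step(two_spheres, 0.0)

    def test_fixed_node_immobile_under_force(self, two_spheres):
        two_spheres.fixed[1] = True
        before = two_spheres.positions[1].copy()
        for _ in range(50):
            mech.integrate_step(two_spheres, 0.05)
        assert np.array_equal(two_spheres.positions[1], before)

    def test_time_advances(self, two_spheres):
        mech.integrate_step(two_spheres, 0.25)
        assert two_spheres.time == pytest.approx(0.25)

    def test_two_attracting_spheres_monotone_approach(self, two_spheres):
        """Distance decreases monotonically towards the rest distance."""
        last = 1.2
        for _ in range(400):
            mech.integrate_step(two_spheres, 0.01)
            d = np.linalg.norm(two_spheres.positions[1] - two_spheres.positions[0])
            assert d <= last + 1e-12
            last = d
        assert last == pytest.approx(1.0, abs=1e-3)


class TestRelax:
    def test_equilibrium_returns_immediately(self, flat_sheet_2d):
        res = mech.relax(flat_sheet_2d, force_tolerance=1e-6)
        assert res.steps == 0 and res.converged

    def test_two_spheres_reach_analytic_equilibrium(self, two_spheres):
        """Final distance equals EQDsum within 1e-6 (analytic fixed point
        of the linear contact law)."""
        res = mech.relax(two_spheres, force_tolerance=5e-7, dt=0.01,
                         max_steps=50_000)
        assert res.converged
        d = np.linalg.norm(res.state.positions[1] - res.state.positions[0])
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_descent_for_pure_pairwise_system(self):
        """Max force is non-increasing during relaxation of a sphere pile."""
        rng = np.random.default_rng(5)
        b = StateBuilder(2)
        for p in rng.uniform(0, 3, (20, 2)):
            b.add_sphere(p, MESENCHYME)
        state = b.build()
        maxima = []

        def cb(s, step):
            fld = mech.total_forces(s, mech.build_neighbor_graph(s))
            maxima.append(np.linalg.norm(fld.forces, axis=1).max())

        mech.relax(state, force_tolerance=1e-3, dt=0.005, max_steps=300,
                   callback=cb)
        diffs = np.diff(maxima)
        assert (diffs <= 1e-9).mean() > 0.95  # allow isolated graph-topology flips

    def test_determinism(self, two_spheres):
        a = mech.relax(two_spheres.copy(), force_tolerance=1e-5, dt=0.01)
        b = mech.relax(two_spheres.copy(), force_tolerance=1e-5, dt=0.01)
        assert np.array_equal(a.state.positions, b.state.positions)
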
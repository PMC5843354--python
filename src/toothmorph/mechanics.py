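"""Node-level force laws and overdamped time integration.

Motion is first order (velocity proportional to force, unit mobility, no
inertia, no thermal noise).  Three force classes act:

* pairwise contact forces between neighbouring nodes: linear repulsion
  below the rest distance ``EQDsum = p_i_EQD + p_j_EQD``, linear adhesion
  (slope set by the adhesion-molecule affinity ``k_ADH``) between the
  rest distance and the cut-off ``ADDsum = p_i_ADD + p_j_ADD``, and zero
  beyond the cut-off;
* an apical-basal spring inside each epithelial cylinder;
* two epithelial bending terms that keep the monolayer smooth (a radial
  term levelling neighbouring cylinders along the shared surface normal)
  and upright (a rotational term tilting each cylinder towards the local
  surface normal).

Sign convention for the pairwise modulus ``f_A``: positive = attraction
(node i is pulled along the unit vector towards j), negative = repulsion.
Both branches vanish at the rest distance; the adhesive branch drops
discontinuously to zero at the cut-off, which is where cells lose
contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .state import AdhesionTable, NodeState, SimulationState

__all__ = [
    "NeighborGraph",
    "ForceField",
    "RelaxResult",
    "build_neighbor_graph",
    "pair_interaction_force",
    "epithelial_spring_force",
    "epithelial_bending_forces",
    "total_forces",
    "integrate_step",
    "relax",
]


@dataclass
class NeighborGraph:
    """Geometric contact graph: node pairs (i < j) with centre distance
    within interaction range, with cached distances and unit vectors
    u_ij (pointing i -> j; u_ji = -u_ij)."""

    pairs: np.ndarray  # (E, 2) int
    dist: np.ndarray  # (E,)
    unit: np.ndarray  # (E, dim), from pairs[:,0] towards pairs[:,1]

    @property
    def n_edges(self) -> int:
        return self.pairs.shape[0]

    def degree(self, n_nodes: int) -> np.ndarray:
        deg = np.zeros(n_nodes, dtype=int)
        np.add.at(deg, self.pairs.ravel(), 1)
        return deg


@dataclass
class ForceField:
    """Per-node force vectors plus the per-edge scalar interaction
    modulus f_A (aligned with the graph's edge list; same-cell edges
    carry 0 because the intracellular spring replaces contact forces)."""

    forces: np.ndarray  # (N, dim)
    edge_modulus: np.ndarray  # (E,)


def build_neighbor_graph(state: SimulationState,
                         rng: np.random.Generator | None = None) -> NeighborGraph:
    """All unordered node pairs with d_ij <= p_i_ADD + p_j_ADD.

    Coincident nodes (d == 0) get a unit vector drawn from ``rng`` (a
    fixed default generator if none is given) so downstream forces stay
    defined; division placement can create near-coincident nodes.
    """
    pos = state.positions
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite node positions")
    tree = cKDTree(pos)
    rmax = 2.0 * float(state.p_ADD.max())
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size == 0:
        dim = state.dim
        return NeighborGraph(
            pairs=np.empty((0, 2), dtype=np.int64),
            dist=np.empty(0),
            unit=np.empty((0, dim)),
        )
    d_vec = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    dist = np.linalg.norm(d_vec, axis=1)
    keep = dist <= state.p_ADD[pairs[:, 0]] + state.p_ADD[pairs[:, 1]]
    pairs, d_vec, dist = pairs[keep], d_vec[keep], dist[keep]
    unit = np.zeros_like(d_vec)
    nz = dist > 0
    unit[nz] = d_vec[nz] / dist[nz, None]
    if np.any(~nz):
        if rng is None:
            rng = np.random.default_rng(0)
        r = rng.normal(size=((~nz).sum(), d_vec.shape[1]))
        unit[~nz] = r / np.linalg.norm(r, axis=1, keepdims=True)
    return NeighborGraph(pairs=pairs, dist=dist, unit=unit)


# ----------------------------------------------------------------------
# scalar (per-pair) API used by tests and documentation examples

def adhesion_strength(expression_i: np.ndarray, expression_j: np.ndarray,
                      adhesion: AdhesionTable) -> float:
    """k_ADH = sum_m sum_n g_im g_jn b_mn."""
    return float(expression_i @ adhesion.b @ expression_j)


def pair_interaction_force(i: NodeState, j: NodeState,
                           adhesion: AdhesionTable) -> float:
    """Signed scalar contact modulus f_A between two neighbouring nodes.

    Positive = attraction, negative = repulsion; zero beyond cut-off.
    """
    d = float(np.linalg.norm(j.position - i.position))
    eqd = i.p_EQD + j.p_EQD
    add = i.p_ADD + j.p_ADD
    if d < eqd:
        return (i.p_REC + j.p_REC) * (d - eqd)
    if d <= add:
        return adhesion_strength(i.expression, j.expression, adhesion) * (d - eqd)
    return 0.0


def epithelial_spring_force(p_EQS: float, apical: NodeState,
                            basal: NodeState) -> tuple[np.ndarray, np.ndarray]:
    """Spring force of an epithelial cylinder on (apical, basal) nodes.

    Modulus k_HOO (d - p_EQS) with k_HOO = p_a_HOO + p_b_HOO, along the
    apical-basal axis; equal magnitude, opposite direction.
    """
    axis = basal.position - apical.position
    d = float(np.linalg.norm(axis))
    if d == 0:
        raise ValueError("zero-length epithelial cylinder: degenerate axis")
    if p_EQS <= 0:
        raise ValueError("spring rest length must be > 0")
    s_hat = axis / d
    f = (apical.p_HOO + basal.p_HOO) * (d - p_EQS)
    return f * s_hat, -f * s_hat


def epithelial_bending_forces(i: NodeState, j: NodeState, axis_i: np.ndarray,
                              axis_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(radial, rotational) bending forces on node i from same-face
    neighbour j.

    f_EST = k_EST (m.c/|m|) m-hat with m = s_ik + s_jl, k_EST = p_i_EST
    + p_j_EST; f_ERP = p_i_ERP (s_ik.c/|s_ik|) c-hat, with c the vector
    from i to j.  Both vanish when the relevant angle is 90 degrees.
    Anti-parallel axes (|m| = 0) are degenerate; the radial term is
    zeroed there.
    """
    c = np.asarray(j.position, dtype=float) - np.asarray(i.position, dtype=float)
    m = np.asarray(axis_i, dtype=float) + np.asarray(axis_j, dtype=float)
    m_norm = np.linalg.norm(m)
    if m_norm == 0:
        f_est = np.zeros_like(c)
    else:
        k_est = i.p_EST + j.p_EST
        f_est = k_est * (m @ c) / m_norm**2 * m
    s_norm = np.linalg.norm(axis_i)
    c_norm = np.linalg.norm(c)
    if s_norm == 0 or c_norm == 0:
        f_erp = np.zeros_like(c)
    else:
        # p_ERP (s.c/|s|) c-hat
        f_erp = i.p_ERP * (np.asarray(axis_i) @ c) / (s_norm * c_norm) * c
    return f_est, f_erp


# ----------------------------------------------------------------------
# vectorized aggregation

def _edge_moduli(state: SimulationState, graph: NeighborGraph) -> np.ndarray:
    """Vectorized pairwise moduli; same-cell (apical/basal partner) edges
    are zeroed because the spring, not contact forces, acts there."""
    if graph.n_edges == 0:
        return np.empty(0)
    a, b = graph.pairs[:, 0], graph.pairs[:, 1]
    d = graph.dist
    eqd = state.p_EQD[a] + state.p_EQD[b]
    add = state.p_ADD[a] + state.p_ADD[b]
    # k_ADH via the 3-molecule affinity table
    k_adh = np.einsum("em,mn,en->e", state.expression[a], state.adhesion.b,
                      state.expression[b])
    f = np.where(
        d < eqd,
        (state.p_REC[a] + state.p_REC[b]) * (d - eqd),
        np.where(d <= add, k_adh * (d - eqd), 0.0),
    )
    f[state.node_cell[a] == state.node_cell[b]] = 0.0
    return f


def total_forces(state: SimulationState, graph: NeighborGraph) -> ForceField:
    """Aggregate contact, spring and bending forces into one field.

    Contact contributions obey action-reaction exactly; fixed nodes are
    masked to zero after summation.
    """
    n, dim = state.n_nodes, state.dim
    forces = np.zeros((n, dim))
    moduli = _edge_moduli(state, graph)
    if graph.n_edges:
        a, b = graph.pairs[:, 0], graph.pairs[:, 1]
        contrib = moduli[:, None] * graph.unit
        np.add.at(forces, a, contrib)
        np.add.at(forces, b, -contrib)

    # apical-basal springs
    epi = np.flatnonzero(state.cell_nodes[:, 1] >= 0)
    if epi.size:
        ap = state.cell_nodes[epi, 0]
        ba = state.cell_nodes[epi, 1]
        axis = state.positions[ba] - state.positions[ap]
        d = np.linalg.norm(axis, axis=1)
        if np.any(d == 0):
            raise ValueError("zero-length epithelial cylinder: degenerate axis")
        s_hat = axis / d[:, None]
        f = (state.p_HOO[ap] + state.p_HOO[ba]) * (d - state.cell_EQS[epi])
        np.add.at(forces, ap, f[:, None] * s_hat)
        np.add.at(forces, ba, -f[:, None] * s_hat)

        # bending: same-face (apical-apical / basal-basal) neighbour pairs
        partner = np.full(n, -1, dtype=np.int64)
        partner[ap] = ba
        partner[ba] = ap
        if graph.n_edges:
            same_face = (
                (partner[a] >= 0)
                & (state.role[a] == state.role[b])
                & (state.node_cell[a] != state.node_cell[b])
            )
            if np.any(same_face):
                ia, ib = a[same_face], b[same_face]
                s_i = state.positions[partner[ia]] - state.positions[ia]
                s_j = state.positions[partner[ib]] - state.positions[ib]
                c = state.positions[ib] - state.positions[ia]
                m = s_i + s_j
                m2 = np.einsum("ed,ed->e", m, m)
                mdc = np.einsum("ed,ed->e", m, c)
                ok = m2 > 0
                k_est = state.p_EST[ia] + state.p_EST[ib]
                coef = np.where(ok, k_est * mdc / np.where(ok, m2, 1.0), 0.0)
                f_est = coef[:, None] * m
                np.add.at(forces, ia, f_est)
                np.add.at(forces, ib, -f_est)
                # rotational term, one-sided per node with its own p_ERP:
                # p_ERP (s.c/|s|) c-hat, so the coefficient on raw c is
                # p_ERP s.c / (|s| |c|)
                c_n = np.sqrt(np.einsum("ed,ed->e", c, c))
                s_i_n = np.linalg.norm(s_i, axis=1)
                s_j_n = np.linalg.norm(s_j, axis=1)
                sdc_i = np.einsum("ed,ed->e", s_i, c)
                sdc_j = np.einsum("ed,ed->e", s_j, -c)
                coef_i = state.p_ERP[ia] * sdc_i / (s_i_n * c_n)
                coef_j = state.p_ERP[ib] * sdc_j / (s_j_n * c_n)
                np.add.at(forces, ia, coef_i[:, None] * c)
                np.add.at(forces, ib, coef_j[:, None] * -c)

    forces[state.fixed] = 0.0
    return ForceField(forces=forces, edge_modulus=moduli)


# ----------------------------------------------------------------------
# integration

def integrate_step(state: SimulationState, dt: float,
                   field: ForceField | None = None,
                   graph: NeighborGraph | None = None,
                   max_displacement: float | None = None) -> SimulationState:
    """One forward-Euler step of the overdamped dynamics (unit mobility).

    Non-fixed nodes move by dt * force, with the per-node displacement
    norm capped (default 0.1 x min p_EQD) to keep the stiff repulsive
    branch stable.  Mutates and returns ``state``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if field is None:
        if graph is None:
            graph = build_neighbor_graph(state)
        field = total_forces(state, graph)
    if max_displacement is None:
        max_displacement = 0.1 * float(state.p_EQD.min())
    step = dt * field.forces
    norms = np.linalg.norm(step, axis=1)
    over = norms > max_displacement
    if np.any(over):
        step[over] *= (max_displacement / norms[over])[:, None]
    step[state.fixed] = 0.0
    state.positions += step
    state.time += dt
    return state


@dataclass
class RelaxResult:
    state: SimulationState
    steps: int
    converged: bool
    max_force: float


def relax(state: SimulationState, force_tolerance: float = 1e-4,
          max_steps: int = 10_000, dt: float = 0.01,
          max_displacement: float | None = None,
          callback=None) -> RelaxResult:
    """Integrate until the maximum per-node force drops below tolerance.

    Returns the first state meeting the tolerance, or the state after
    ``max_steps`` with ``converged=False``.  ``callback(state, step)``
    runs after every step (used to record relaxation frames).
    """
    steps = 0
    while True:
        graph = build_neighbor_graph(state)
        field = total_forces(state, graph)
        max_f = float(np.linalg.norm(field.forces, axis=1).max(initial=0.0))
        if max_f < force_tolerance:
            return RelaxResult(state, steps, True, max_f)
        if steps >= max_steps:
            return RelaxResult(state, steps, False, max_f)
        integrate_step(state, dt, field=field, max_displacement=max_displacement)
        steps += 1
        if callback is not None:
            callback(state, steps)
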
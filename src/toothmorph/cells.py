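"""Cell-cycle progression, division, and the knot-derived signal field.

Each cell carries a cycle-phase variable P_PHA in [0, 1] that advances
at the tissue-specific rate s (units h^-1, i.e. the inverse of the cell
cycle length); when it reaches 1 the cell divides and both daughters
restart at 0.  Enamel-knot cells never divide.

Three proliferation hypotheses are supported:

I   uniform per-tissue rates everywhere;
II  proliferation only where the diffusible signal secreted by the
    enamel knot exceeds a threshold concentration;
III uniform proliferation in the epithelium and suprabasal layer,
    signal-gated proliferation in the mesenchyme.

The signal is modelled as a quasi-steady exponential kernel
c(x) = sum_sources exp(-dist/lambda): only the position of the c = theta
level set matters to the model's logic, so explicit
production/diffusion/decay dynamics are not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .state import APICAL, BASAL, MESENCHYME, SimulationState

__all__ = [
    "GrowthConfig",
    "update_signal",
    "proliferation_eligibility",
    "advance_cycle",
    "divide_cell",
    "divide_cells",
]

HYPOTHESES = ("I", "II", "III")


@dataclass(frozen=True)
class GrowthConfig:
    """Proliferation hypothesis and per-tissue rates.

    Rates are in h^-1 (inverse cell-cycle length).  ``signal_threshold``
    (theta) and ``signal_length_scale`` (lambda, cell diameters) shape
    the knot signal's reach; ``division_placement_radius`` (epsilon) is
    the maximum parent-daughter offset.
    """

    hypothesis: str = "III"
    s_epi: float = 0.063
    s_sup: float = 0.021
    s_mes: float = 0.182
    signal_threshold: float = 0.25
    signal_length_scale: float = 2.5
    division_placement_radius: float = 0.25

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if min(self.s_epi, self.s_sup, self.s_mes) < 0:
            raise ValueError("proliferation rates must be >= 0")
        if self.signal_threshold < 0:
            raise ValueError("signal threshold must be >= 0")
        if self.signal_length_scale <= 0:
            raise ValueError("signal length scale must be > 0")
        if self.division_placement_radius <= 0:
            raise ValueError("division placement radius must be > 0")

    def rate(self, tissue: np.ndarray) -> np.ndarray:
        return np.choose(tissue, [self.s_epi, self.s_sup, self.s_mes])


def update_signal(state: SimulationState, config: GrowthConfig) -> np.ndarray:
    """Per-cell concentration of the knot signal.

    Additive over sources (one per enamel-knot cell, at the cell
    centroid), strictly decreasing with distance from an isolated
    source, and exactly zero when no knot exists.
    """
    if config.signal_length_scale <= 0:
        raise ValueError("signal length scale must be > 0")
    centroids = state.cell_centroids()
    sources = centroids[state.cell_knot]
    field = np.zeros(state.n_cells)
    if sources.shape[0] == 0:
        return field
    # pairwise distances cell x source (sources are few)
    d = np.linalg.norm(centroids[:, None, :] - sources[None, :, :], axis=2)
    return np.exp(-d / config.signal_length_scale).sum(axis=1)


def proliferation_eligibility(state: SimulationState, config: GrowthConfig,
                              signal: np.ndarray | None = None) -> np.ndarray:
    """Boolean eligibility per cell under the configured hypothesis.

    Knot cells are never eligible.  Hypothesis II gates every tissue on
    signal >= threshold; III gates the mesenchyme only.
    """
    if config.hypothesis == "I":
        gated = np.zeros(state.n_cells, dtype=bool)
    else:
        if signal is None:
            signal = update_signal(state, config)
        below = signal < config.signal_threshold
        if config.hypothesis == "II":
            gated = below
        else:  # III
            gated = below & (state.cell_tissue == MESENCHYME)
    return ~state.cell_knot & ~gated


def advance_cycle(state: SimulationState, dt: float, config: GrowthConfig,
                  signal: np.ndarray | None = None) -> np.ndarray:
    """Advance P_PHA by s_tissue * dt for eligible cells (in place).

    Returns the indices of cells whose phase crossed 1 (they are due to
    divide; ``divide_cells`` resets them).  Phases are held at 1 until
    the division is executed so the state stays valid.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    eligible = proliferation_eligibility(state, config, signal)
    rates = config.rate(state.cell_tissue)
    state.cell_phase[eligible] += rates[eligible] * dt
    # tolerance absorbs floating-point accumulation over 1/(s dt) steps
    due = np.flatnonzero(state.cell_phase >= 1.0 - 1e-9)
    state.cell_phase[due] = 1.0
    return due


def _tangent_offset(state: SimulationState, axis: np.ndarray, eps: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Random in-plane offset perpendicular to an epithelial axis."""
    if state.dim == 2:
        t = np.array([-axis[1], axis[0]])
        t /= np.linalg.norm(t)
        return eps * rng.choice([-1.0, 1.0]) * t
    # 3D: random direction in the tangent plane of the axis
    n = axis / np.linalg.norm(axis)
    v = rng.normal(size=3)
    v -= (v @ n) * n
    nv = np.linalg.norm(v)
    if nv == 0:  # measure-zero draw
        v = np.array([n[1] - n[2], n[2] - n[0], n[0] - n[1]])
        nv = np.linalg.norm(v)
    return eps * v / nv


def divide_cells(state: SimulationState, cell_ids: np.ndarray,
                 rng: np.random.Generator,
                 config: GrowthConfig) -> SimulationState:
    """Divide the listed cells, appending daughters to the arrays.

    Daughters inherit tissue, mechanical parameters and expression.
    Sphere daughters are placed at a uniform-random offset of length
    <= epsilon; epithelial daughters are new cylinders offset within the
    local epithelial tangent plane with the parent's axis copied (the
    monolayer is preserved by inserting in-plane, not along the axis).
    Both parent and daughter restart the cycle at P_PHA = 0.
    Deterministic for a given generator state.
    """
    eps = config.division_placement_radius
    new_pos, new_role, new_cell_of_node, new_fixed = [], [], [], []
    new_tissue, new_knot, new_nodes, new_eqs = [], [], [], []
    new_param_src = []  # parent node index whose parameters are copied
    n_nodes = state.n_nodes
    n_cells = state.n_cells
    for cid in np.atleast_1d(np.asarray(cell_ids, dtype=int)):
        if state.cell_knot[cid]:
            raise ValueError(f"enamel-knot cell {cid} cannot divide")
        state.cell_phase[cid] = 0.0
        tissue = int(state.cell_tissue[cid])
        daughter = n_cells + len(new_tissue)
        ap, ba = state.cell_nodes[cid]
        if ba < 0:  # sphere
            u = rng.normal(size=state.dim)
            u /= np.linalg.norm(u)
            offset = eps * rng.uniform(0.3, 1.0) * u
            nid = n_nodes + len(new_pos)
            new_pos.append(state.positions[ap] + offset)
            new_role.append(int(state.role[ap]))
            new_cell_of_node.append(daughter)
            new_fixed.append(False)
            new_param_src.append(ap)
            new_nodes.append((nid, -1))
            new_eqs.append(np.nan)
        else:
            axis = state.positions[ba] - state.positions[ap]
            offset = _tangent_offset(state, axis, eps, rng)
            na = n_nodes + len(new_pos)
            new_pos.append(state.positions[ap] + offset)
            new_pos.append(state.positions[ba] + offset)
            new_role.extend([APICAL, BASAL])
            new_cell_of_node.extend([daughter, daughter])
            new_fixed.extend([False, False])
            new_param_src.extend([ap, ba])
            new_nodes.append((na, na + 1))
            new_eqs.append(float(state.cell_EQS[cid]))
        new_tissue.append(tissue)
        new_knot.append(False)

    if not new_tissue:
        return state
    src = np.asarray(new_param_src, dtype=int)
    state.positions = np.vstack([state.positions, np.asarray(new_pos)])
    state.role = np.concatenate([state.role, np.asarray(new_role, dtype=np.int8)])
    state.node_cell = np.concatenate(
        [state.node_cell, np.asarray(new_cell_of_node, dtype=np.int64)])
    state.fixed = np.concatenate([state.fixed, np.asarray(new_fixed, dtype=bool)])
    for name in ("p_REC", "p_EQD", "p_ADD", "p_HOO", "p_EST", "p_ERP"):
        arr = getattr(state, name)
        setattr(state, name, np.concatenate([arr, arr[src]]))
    state.expression = np.vstack([state.expression, state.expression[src]])
    state.cell_tissue = np.concatenate(
        [state.cell_tissue, np.asarray(new_tissue, dtype=np.int8)])
    state.cell_knot = np.concatenate(
        [state.cell_knot, np.asarray(new_knot, dtype=bool)])
    state.cell_phase = np.concatenate([state.cell_phase, np.zeros(len(new_tissue))])
    state.cell_nodes = np.vstack(
        [state.cell_nodes, np.asarray(new_nodes, dtype=np.int64)])
    state.cell_EQS = np.concatenate([state.cell_EQS, np.asarray(new_eqs)])
    return state


def divide_cell(state: SimulationState, cell_id: int, rng: np.random.Generator,
                config: GrowthConfig | None = None) -> SimulationState:
    """Divide a single cell (see :func:`divide_cells`)."""
    return divide_cells(state, np.array([cell_id]), rng,
                        config or GrowthConfig())
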
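"""In-silico experimental battery on the tooth-germ model.

Full bud-to-cap runs, parameter screens over growth and adhesion,
morphometric measurements of the simulated germ (growth angle, loop
depths, growth curves), trajectory tracking, the epithelium-mesenchyme
separation assay, contact-stress maps, and the closed-form geometric
model of the AP/BL loop-elongation asymmetry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from . import mechanics
from .cells import GrowthConfig, advance_cycle, divide_cells, update_signal
from .morphometrics import LandmarkConfiguration, LandmarkSeries
from .state import BASAL, EPITHELIUM, MESENCHYME, SUPRABASAL, SimulationState
from .synthetic import ReferenceCurves

__all__ = [
    "RunConfig",
    "GermMeasurements",
    "run_simulation",
    "measure_growth_angle",
    "measure_loop_lengths",
    "measure_germ",
    "measure_growth_curves",
    "curve_error",
    "parameter_screen",
    "tail_mean_growth_angle",
    "track_cells",
    "tip_retention",
    "separation_assay",
    "contact_stress_map",
    "geometric_elongation",
]


class MeasurementError(ValueError):
    """A morphometric quantity is undefined on this state."""


@dataclass(frozen=True)
class RunConfig:
    """One simulation run: growth rules, horizon (hours), stepping.

    Mechanics are treated quasi-statically: after every growth step of
    ``dt_growth`` the node system is relaxed with ``mech_substeps``
    capped Euler steps of pseudo-time ``dt_mech`` (the biological clock
    advances only by ``dt_growth``).
    """

    growth: GrowthConfig
    total_time: float
    seed: int
    dt_growth: float = 0.25
    mech_substeps: int = 30
    dt_mech: float = 0.01
    snapshot_interval: float = 2.0
    max_cells: int = 20_000

    def __post_init__(self):
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        if self.dt_growth <= 0 or self.dt_mech <= 0:
            raise ValueError("time steps must be > 0")


def _mech_settle(state: SimulationState, substeps: int, dt: float) -> None:
    t0 = state.time
    for _ in range(substeps):
        graph = mechanics.build_neighbor_graph(state)
        fld = mechanics.total_forces(state, graph)
        mechanics.integrate_step(state, dt, field=fld)
    state.time = t0


def run_simulation(state: SimulationState, config: RunConfig) -> list[SimulationState]:
    """Simulate growth + mechanics; returns snapshots (copies) at the
    configured interval, always including the initial and final states.

    Deterministic for a given config and seed.  Aborts with a diagnostic
    on numerical blow-up (non-finite coordinates) or runaway growth
    (cell count above ``config.max_cells``).
    """
    state = state.copy()
    rng = np.random.default_rng(config.seed)
    snapshots = [state.copy()]
    n_steps = int(round(config.total_time / config.dt_growth))
    next_snap = config.snapshot_interval
    growth = config.growth
    for _ in range(n_steps):
        signal = None
        if growth.hypothesis != "I":
            signal = update_signal(state, growth)
        due = advance_cycle(state, config.dt_growth, growth, signal)
        if due.size:
            divide_cells(state, due, rng, growth)
            if state.n_cells > config.max_cells:
                raise RuntimeError(
                    f"runaway growth: {state.n_cells} cells exceeds the "
                    f"configured maximum {config.max_cells}")
        _mech_settle(state, config.mech_substeps, config.dt_mech)
        state.time += config.dt_growth
        if not np.all(np.isfinite(state.positions)):
            raise RuntimeError(
                f"numerical blow-up at t={state.time:.2f} h: non-finite "
                "node positions")
        if state.time >= next_snap - 1e-9:
            snapshots.append(state.copy())
            next_snap += config.snapshot_interval
    if snapshots[-1].time < state.time:
        snapshots.append(state.copy())
    return snapshots


# ----------------------------------------------------------------------
# germ measurements

def _depth_axis(state: SimulationState) -> int:
    """Index of the depth coordinate (y in 2D, z in 3D); depth grows
    more negative into the jaw."""
    return 1 if state.dim == 2 else 2


def _knot_centroid(state: SimulationState) -> np.ndarray:
    """Centroid of the knot cells' basal nodes (the angle vertex sits on
    the epithelial-mesenchymal interface)."""
    knots = np.flatnonzero(state.cell_knot)
    if knots.size == 0:
        raise MeasurementError("no enamel knot in this state")
    return state.positions[state.cell_nodes[knots, 1]].mean(axis=0)


def _frontal_tips(state: SimulationState):
    """(knot centroid, left tip position, right tip position) in the
    frontal plane; tips are the deepest non-fixed basal epithelial nodes
    on each bucco-lingual side of the knot (within a mid-frontal slab of
    two cell spacings in 3D)."""
    knot = _knot_centroid(state)
    dax = _depth_axis(state)
    basal = np.flatnonzero(
        (state.role == BASAL)
        & ~state.fixed
        & ~state.cell_knot[state.node_cell]
    )
    pos = state.positions[basal]
    if state.dim == 3:
        slab = np.abs(pos[:, 1] - knot[1]) <= 2.0 * float(np.median(2 * state.p_EQD))
        basal, pos = basal[slab], pos[slab]
    left = pos[:, 0] < knot[0]
    right = pos[:, 0] > knot[0]
    if not left.any() or not right.any():
        raise MeasurementError("missing epithelium on one side of the knot")
    il = basal[left][np.argmin(pos[left][:, dax])]
    ir = basal[right][np.argmin(pos[right][:, dax])]
    return knot, state.positions[il], state.positions[ir], int(il), int(ir)


def measure_growth_angle(state: SimulationState) -> float:
    """Growth angle of the cervical loops, degrees in [0, 180]: the
    angle at the knot centroid between the vectors to the two loop tips
    in the frontal plane (small = loops pointing down, 180 = lateral)."""
    knot, tip_l, tip_r, _, _ = _frontal_tips(state)
    if state.dim == 3:  # project to the frontal (x, z) plane
        sel = [0, 2]
        knot, tip_l, tip_r = knot[sel], tip_l[sel], tip_r[sel]
    v1, v2 = tip_l - knot, tip_r - knot
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_loop_lengths(state: SimulationState) -> dict[str, float]:
    """Depth of the deepest non-fixed basal epithelial node below the
    fixed epithelial border plane, per quadrant around the knot
    (buccal +x, lingual -x, anterior +y, posterior -y).  3D only."""
    if state.dim != 3:
        raise MeasurementError("loop lengths are defined on 3D states")
    knot = _knot_centroid(state)
    border = (state.role == BASAL) & state.fixed
    if not border.any():
        raise MeasurementError("no fixed epithelial border")
    z_border = float(state.positions[border][:, 2].mean())
    basal = (state.role == BASAL) & ~state.fixed
    pos = state.positions[basal]
    dx = pos[:, 0] - knot[0]
    dy = pos[:, 1] - knot[1]
    quadrants = {
        "buccal": (dx >= np.abs(dy)),
        "lingual": (-dx >= np.abs(dy)),
        "anterior": (dy > np.abs(dx)),
        "posterior": (-dy > np.abs(dx)),
    }
    out = {}
    for name, sel in quadrants.items():
        if not sel.any():
            raise MeasurementError(f"no epithelium in the {name} quadrant")
        out[name] = float(z_border - pos[sel][:, 2].min())
    return out


@dataclass
class GermMeasurements:
    """Morphometric summary of one simulated germ."""

    growth_angle: float
    loop_lengths: dict[str, float] = field(default_factory=dict)
    dental_mesenchyme_height: float = np.nan

    def as_dict(self) -> dict[str, float]:
        out = {"growth_angle": self.growth_angle,
               "dental_mesenchyme_height": self.dental_mesenchyme_height}
        out.update({f"loop_{k}": v for k, v in self.loop_lengths.items()})
        return out


def measure_germ(state: SimulationState) -> GermMeasurements:
    angle = measure_growth_angle(state)
    knot, tip_l, tip_r, _, _ = _frontal_tips(state)
    dax = _depth_axis(state)
    knot_cells = np.flatnonzero(state.cell_knot)
    knot_basal = state.positions[state.cell_nodes[knot_cells, 1]]
    base = float(knot_basal[:, dax].min())
    height = base - 0.5 * (tip_l[dax] + tip_r[dax])
    loops = measure_loop_lengths(state) if state.dim == 3 else {
        "left": float(-tip_l[dax]), "right": float(-tip_r[dax])}
    return GermMeasurements(growth_angle=angle, loop_lengths=loops,
                            dental_mesenchyme_height=float(height))


# ----------------------------------------------------------------------
# growth curves (2D)

def _basal_chain_length(state: SimulationState) -> float:
    """Epithelial perimeter: greedy nearest-neighbour path through the
    basal nodes, starting from the leftmost one."""
    basal = np.flatnonzero(state.role == BASAL)
    pos = state.positions[basal]
    if len(basal) < 2:
        return 0.0  # no epithelial chain in this state
    order = [int(np.argmin(pos[:, 0]))]
    remaining = set(range(len(basal))) - set(order)
    total = 0.0
    cutoff = 2.0 * float(2 * state.p_ADD.max())
    while remaining:
        cur = pos[order[-1]]
        rem = np.fromiter(remaining, dtype=int)
        d = np.linalg.norm(pos[rem] - cur, axis=1)
        j = int(np.argmin(d))
        if d[j] > cutoff:
            break
        total += float(d[j])
        order.append(int(rem[j]))
        remaining.discard(int(rem[j]))
    return total


def _suprabasal_area(state: SimulationState, edge_slack: float = 1.05) -> float:
    """Suprabasal surface area: Delaunay triangulation over suprabasal +
    epithelial-basal node positions, keeping triangles whose edges are
    within ``edge_slack`` times the pairwise contact cut-off (the slack
    admits diagonal contacts of square/jittered packings)."""
    tissue = state.node_tissue()
    sel = np.flatnonzero((tissue == SUPRABASAL) | (state.role == BASAL))
    pts = state.positions[sel]
    if len(pts) < 3:
        raise MeasurementError("fewer than 3 nodes for triangulation")
    tri = Delaunay(pts)
    add = state.p_ADD[sel]
    simplices = tri.simplices
    keep = np.ones(len(simplices), dtype=bool)
    for a, b in ((0, 1), (1, 2), (0, 2)):
        i, j = simplices[:, a], simplices[:, b]
        d = np.linalg.norm(pts[i] - pts[j], axis=1)
        keep &= d <= edge_slack * (add[i] + add[j])
    kept = simplices[keep]
    v1 = pts[kept[:, 1]] - pts[kept[:, 0]]
    v2 = pts[kept[:, 2]] - pts[kept[:, 0]]
    return float(0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]).sum())


def measure_growth_curves(snapshots: list[SimulationState],
                          reference_unit: float = 10.0,
                          edge_slack: float = 1.05) -> ReferenceCurves:
    """Model growth curves over percent time from 2D snapshots: the
    epithelial perimeter and the suprabasal area, each divided by the
    declared reference unit (length, and length squared)."""
    if not snapshots:
        raise ValueError("no snapshots")
    if snapshots[0].dim != 2:
        raise MeasurementError("growth curves are defined on 2D snapshots")
    times = np.array([s.time for s in snapshots])
    span = times[-1] - times[0]
    pct = 100.0 * (times - times[0]) / span if span > 0 else np.linspace(
        0, 100, len(times))
    perim = np.array([_basal_chain_length(s) for s in snapshots]) / reference_unit
    area = np.array([_suprabasal_area(s, edge_slack) for s in snapshots]) / (
        reference_unit**2)
    # guard against duplicated time stamps
    pct = np.maximum.accumulate(pct + 1e-9 * np.arange(len(pct)))
    return ReferenceCurves(pct, perim, area)


def curve_error(model: ReferenceCurves, reference: ReferenceCurves,
                normalize: bool = True) -> float:
    """Pooled RMSE between model and reference curves after per-curve
    normalization (each curve divided by its own mean): symmetric,
    nonnegative, zero iff identical on the common grid."""
    grid = np.union1d(model.percent_time, reference.percent_time)
    grid = grid[(grid >= max(model.percent_time[0], reference.percent_time[0]))
                & (grid <= min(model.percent_time[-1], reference.percent_time[-1]))]
    total = 0.0
    for attr in ("perimeter", "area"):
        a = np.interp(grid, model.percent_time, getattr(model, attr))
        b = np.interp(grid, reference.percent_time, getattr(reference, attr))
        if normalize:
            a = a / a.mean()
            b = b / b.mean()
        total += float(np.mean((a - b) ** 2))
    return float(np.sqrt(total))


# ----------------------------------------------------------------------
# parameter screens

_ADHESION_KEYS = {
    "b_EE": (EPITHELIUM, EPITHELIUM),
    "b_ES": (EPITHELIUM, SUPRABASAL),
    "b_EM": (EPITHELIUM, MESENCHYME),
    "b_SS": (SUPRABASAL, SUPRABASAL),
    "b_SM": (SUPRABASAL, MESENCHYME),
    "b_MM": (MESENCHYME, MESENCHYME),
}
_GROWTH_KEYS = ("s_epi", "s_sup", "s_mes")


def _loops_present(state: SimulationState, margin: float = 1.0) -> bool:
    """Loops are called present when both frontal tips descend below the
    knot base by at least ``margin`` cell diameters."""
    knot, tip_l, tip_r, _, _ = _frontal_tips(state)
    dax = _depth_axis(state)
    knot_cells = np.flatnonzero(state.cell_knot)
    base = float(state.positions[state.cell_nodes[knot_cells, 1]][:, dax].min())
    return bool(tip_l[dax] < base - margin and tip_r[dax] < base - margin)


def tail_mean_growth_angle(snapshots: list[SimulationState],
                           window: int = 5) -> float:
    """Growth angle averaged over the final ``window`` snapshots.

    Division events displace single nodes by up to a cell radius, so the
    instantaneous angle of a growing germ carries a few degrees of
    discretization noise; averaging over the tail of the run is the
    endpoint estimator the screens report."""
    tail = snapshots[-window:]
    return float(np.mean([measure_growth_angle(s) for s in tail]))


def parameter_screen(base_state: SimulationState, grid: dict[str, list],
                     base_config: RunConfig,
                     reference: ReferenceCurves | None = None) -> pd.DataFrame:
    """One full run + germ measurements per grid combination.

    ``grid`` maps parameter names (s_epi/s_sup/s_mes and/or the b_*
    adhesion entries) to value lists; every combination is run with a
    per-row seed derived from the base seed and the grid index, and the
    result table carries the parameters, the germ measurements, the
    morphology flags and (when a reference is given) the curve-fit
    error.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    for key in grid:
        if key not in _ADHESION_KEYS and key not in _GROWTH_KEYS:
            raise ValueError(f"unknown screen parameter {key!r}")
    names = list(grid)
    rows = []
    for idx, combo in enumerate(itertools.product(*(grid[k] for k in names))):
        params = dict(zip(names, combo))
        state = base_state.copy()
        adhesion = state.adhesion
        for key, value in params.items():
            if key in _ADHESION_KEYS:
                adhesion = adhesion.with_pair(*_ADHESION_KEYS[key], value)
        state.adhesion = adhesion
        growth = replace(base_config.growth,
                         **{k: v for k, v in params.items() if k in _GROWTH_KEYS})
        config = replace(base_config, growth=growth,
                         seed=base_config.seed + idx)
        snapshots = run_simulation(state, config)
        final = snapshots[-1]
        row = dict(params)
        row["seed"] = config.seed
        row.update(measure_germ(final).as_dict())
        row["growth_angle_tail"] = tail_mean_growth_angle(snapshots)
        row["loops_present"] = _loops_present(final)
        if reference is not None and final.dim == 2:
            row["curve_error"] = curve_error(
                measure_growth_curves(snapshots), reference)
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# trajectories

def track_cells(snapshots: list[SimulationState],
                cell_ids: np.ndarray) -> np.ndarray:
    """(n_frames, n_cells, dim) positions of the tracked cells' first
    nodes (cell indices are stable: arrays are append-only)."""
    cell_ids = np.asarray(cell_ids, dtype=int)
    if np.any(cell_ids >= snapshots[0].n_cells):
        raise ValueError("tracked cells must exist at the first frame")
    return np.stack([
        s.positions[s.cell_nodes[cell_ids, 0]] for s in snapshots
    ])


def tip_cells(state: SimulationState, radius: float = 1.5) -> np.ndarray:
    """Epithelial (non-knot) cells whose basal node lies within
    ``radius`` of either cervical-loop tip."""
    _, tip_l, tip_r, _, _ = _frontal_tips(state)
    epi = np.flatnonzero((state.cell_tissue == EPITHELIUM) & ~state.cell_knot)
    basal_pos = state.positions[state.cell_nodes[epi, 1]]
    d = np.minimum(np.linalg.norm(basal_pos - tip_l, axis=1),
                   np.linalg.norm(basal_pos - tip_r, axis=1))
    return epi[d <= radius]


def tip_retention(snapshots: list[SimulationState],
                  cell_ids: np.ndarray | None = None,
                  radius: float = 1.5) -> float:
    """Fraction of the cells initially at a loop tip that are still
    within ``radius`` of a tip at the final frame."""
    first, last = snapshots[0], snapshots[-1]
    if cell_ids is None:
        cell_ids = tip_cells(first, radius)
    cell_ids = np.asarray(cell_ids, dtype=int)
    if cell_ids.size == 0:
        raise MeasurementError("no cells at the loop tips in the first frame")
    _, tip_l, tip_r, _, _ = _frontal_tips(last)
    pos = last.positions[last.cell_nodes[cell_ids, 1]]
    d = np.minimum(np.linalg.norm(pos - tip_l, axis=1),
                   np.linalg.norm(pos - tip_r, axis=1))
    return float(np.mean(d <= radius))


# ----------------------------------------------------------------------
# separation assay

def _mesenchyme_width(state: SimulationState) -> float:
    """Bounding width of all mesenchymal nodes."""
    mes = state.node_tissue() == MESENCHYME
    x = state.positions[mes][:, 0]
    return float(x.max() - x.min())


def _follicular_width(state: SimulationState, depth_cut: float) -> float:
    """Bounding width of the follicular mesenchyme: the mesenchyme
    flanking the germ above ``depth_cut`` (the knot-base depth of the
    intact cap), whose recoil towards the mid line the assay probes."""
    dax = _depth_axis(state)
    mes = (state.node_tissue() == MESENCHYME) & (state.positions[:, dax] > depth_cut)
    if mes.sum() < 2:
        return 0.0
    x = state.positions[mes][:, 0]
    return float(x.max() - x.min())


def _material_landmarks(state: SimulationState, tip_cells_lr, frame: int
                        ) -> LandmarkConfiguration:
    """The assay's 4-landmark suite on a 2D state: outer junctions of
    the epithelium with the fixed border (1, 4) and the two loop tips
    (2, 3).  Because no growth occurs during the assay, the tips are the
    material cells that formed the curvature maxima of the intact cap
    (the anatomical loci a digitizer would follow through the frames)."""
    il, ir = tip_cells_lr
    tip_l = state.positions[state.cell_nodes[il, 1]]
    tip_r = state.positions[state.cell_nodes[ir, 1]]
    border = (state.role == BASAL) & state.fixed
    bpos = state.positions[border]
    lm1 = bpos[np.argmin(bpos[:, 0])]
    lm4 = bpos[np.argmax(bpos[:, 0])]
    return LandmarkConfiguration(np.stack([lm1, tip_l, tip_r, lm4]),
                                 specimen="model", frame=frame, replicate=0)


def _material_angle(state: SimulationState, tip_cells_lr) -> float:
    """Growth angle at the knot using the tracked material tips."""
    knot = _knot_centroid(state)
    il, ir = tip_cells_lr
    tip_l = state.positions[state.cell_nodes[il, 1]]
    tip_r = state.positions[state.cell_nodes[ir, 1]]
    if state.dim == 3:
        sel = [0, 2]
        knot, tip_l, tip_r = knot[sel], tip_l[sel], tip_r[sel]
    v1, v2 = tip_l - knot, tip_r - knot
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class SeparationResult:
    """Before/after comparison of the in-silico separation.

    ``angle_before``/``angle_after`` follow the material loop tips of
    the intact cap; ``width_before``/``width_after`` are follicular
    mesenchyme bounding widths (``total_width_*`` cover the whole
    mesenchyme)."""

    before: GermMeasurements
    after: GermMeasurements
    angle_before: float
    angle_after: float
    width_before: float
    width_after: float
    total_width_before: float
    total_width_after: float
    snapshots: list[SimulationState]
    landmarks: LandmarkSeries
    converged: bool


def separation_assay(cap_state: SimulationState,
                     force_tolerance: float = 0.05,
                     max_steps: int = 8000,
                     frame_stride: int = 60,
                     dt: float = 0.01,
                     pre_relax: bool = True) -> SeparationResult:
    """In-silico epithelium-mesenchyme separation.

    The cap-stage 2D state is first brought to mechanical equilibrium
    (the ex-vivo tissue is quiescent before the enzyme acts), then the
    epithelial-mesenchymal adhesion b_EM is set to zero and the system
    relaxed again with growth disabled (the ex-vivo deformation is far
    faster than growth).  Reports the growth angle at the tracked loop
    tips and the follicular-mesenchyme bounding width before and after,
    plus the 4-landmark series of the relaxation frames.
    """
    state = cap_state.copy()
    if pre_relax:
        mechanics.relax(state, force_tolerance=force_tolerance,
                        max_steps=max_steps, dt=dt)
    before = measure_germ(state)
    knot0, _, _, il, ir = _frontal_tips(state)
    tips = (int(state.node_cell[il]), int(state.node_cell[ir]))
    depth_cut = float(knot0[_depth_axis(state)])
    angle_before = _material_angle(state, tips)
    width_before = _follicular_width(state, depth_cut)
    total_before = _mesenchyme_width(state)
    state.adhesion = state.adhesion.with_pair(EPITHELIUM, MESENCHYME, 0.0)

    frames = [state.copy()]
    lms = [_material_landmarks(state, tips, 0)]

    def record(s, step):
        if step % frame_stride == 0:
            frames.append(s.copy())
            lms.append(_material_landmarks(s, tips, len(lms)))

    result = mechanics.relax(state, force_tolerance=force_tolerance,
                             max_steps=max_steps, dt=dt, callback=record)
    frames.append(state.copy())
    lms.append(_material_landmarks(state, tips, len(lms)))
    return SeparationResult(
        before=before,
        after=measure_germ(state),
        angle_before=angle_before,
        angle_after=_material_angle(state, tips),
        width_before=width_before,
        width_after=_follicular_width(state, depth_cut),
        total_width_before=total_before,
        total_width_after=_mesenchyme_width(state),
        snapshots=frames,
        landmarks=LandmarkSeries(lms, specimen="model", replicate=0),
        converged=result.converged,
    )


# ----------------------------------------------------------------------
# contact stress map

def contact_stress_map(state: SimulationState) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-contact scalar stress f_A (tension positive, compression
    negative) with midpoint and direction for rendering, plus the
    per-epithelial-cell average of all contact forces acting on it."""
    graph = mechanics.build_neighbor_graph(state)
    fld = mechanics.total_forces(state, graph)
    a, b = graph.pairs[:, 0], graph.pairs[:, 1]
    keep = state.node_cell[a] != state.node_cell[b]
    a, b = a[keep], b[keep]
    stress = fld.edge_modulus[keep]
    mid = 0.5 * (state.positions[a] + state.positions[b])
    direction = graph.unit[keep]
    cols = {"node_i": a, "node_j": b, "stress": stress}
    axes = "xyz"[: state.dim]
    for d, ax in enumerate(axes):
        cols[f"mid_{ax}"] = mid[:, d]
        cols[f"dir_{ax}"] = direction[:, d]
    edges = pd.DataFrame(cols)

    # per-epithelial-cell mean of incident contact stresses
    cell_a = state.node_cell[a]
    cell_b = state.node_cell[b]
    sums = np.zeros(state.n_cells)
    counts = np.zeros(state.n_cells)
    np.add.at(sums, cell_a, stress)
    np.add.at(sums, cell_b, stress)
    np.add.at(counts, cell_a, 1)
    np.add.at(counts, cell_b, 1)
    epi = np.flatnonzero(state.cell_tissue == EPITHELIUM)
    with np.errstate(invalid="ignore"):
        means = np.where(counts[epi] > 0, sums[epi] / counts[epi], np.nan)
    per_cell = pd.DataFrame({"cell_id": epi, "mean_stress": means})
    return edges, per_cell


# ----------------------------------------------------------------------
# geometric model of the AP/BL asymmetry

@dataclass
class GeometricElongation:
    """Closed-form loop-elongation model for an elongated germ seen from
    below: the BL portion is a rectangle of fixed length (area
    proportional to r_BL), the AP portion a circular segment (area
    proportional to r_AP^2).  With area growing as e^{gt}, r_BL grows as
    e^{gt} and r_AP as e^{gt/2}."""

    time: np.ndarray
    r_ap: np.ndarray
    r_bl: np.ndarray
    exponent_ap: float
    exponent_bl: float

    @property
    def exponent_ratio(self) -> float:
        return self.exponent_ap / self.exponent_bl


def geometric_elongation(g: float, r_ap0: float = 1.0, r_bl0: float = 1.0,
                         duration: float = 4.0,
                         n_points: int = 60) -> GeometricElongation:
    if g < 0:
        raise ValueError("areal growth rate must be >= 0")
    t = np.linspace(0.0, duration, n_points)
    r_bl = r_bl0 * np.exp(g * t)
    r_ap = r_ap0 * np.exp(0.5 * g * t)
    if g == 0:
        exp_ap = exp_bl = 0.0
    else:
        exp_bl = float(np.polyfit(t, np.log(r_bl), 1)[0])
        exp_ap = float(np.polyfit(t, np.log(r_ap), 1)[0])
    return GeometricElongation(t, r_ap, r_bl, exp_ap, exp_bl)
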
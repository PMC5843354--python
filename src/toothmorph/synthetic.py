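"""Synthetic inputs: bud-stage initial geometries, reference growth
curves, and digitized-landmark series.

Everything the pipeline consumes is generated here, with no downloads:

* bud-stage initial conditions in 3D (dome-shaped epithelial monolayer
  over a suprabasal fill and a mesenchymal slab, with a fixed border
  ring and a mid-line enamel knot) and their restriction to a frontal
  2D plane;
* smooth exponential-like growth curves of epithelial perimeter and
  suprabasal area over percent developmental time, standing in for
  time-lapse measurements digitized from video (the regime the fitting
  machinery must discriminate: the epithelium outgrows the suprabasal
  layer);
* 2D 4-landmark time series with digitizing replicates, emulating the
  tissue-separation assay's digitization design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from . import mechanics
from .morphometrics import LandmarkConfiguration, LandmarkSeries
from .state import (
    MESENCHYME,
    SUPRABASAL,
    AdhesionTable,
    MechanicalDefaults,
    SimulationState,
    StateBuilder,
)

__all__ = [
    "BudGeometry",
    "ReferenceCurves",
    "preset_geometry",
    "build_bud_3d",
    "build_bud_2d",
    "synth_reference_curves",
    "synth_landmark_series",
]


@dataclass(frozen=True)
class BudGeometry:
    """Bud-stage geometry in model length units (1 = cell diameter).

    The epithelial pocket's semi-axes are the half-lengths minus
    ``dome_margin`` (a flat anchoring rim of equal width on every side);
    the border of the flat epithelium and the uppermost suprabasal layer
    are fixed in space (the physical barrier of the surrounding oral
    epithelium), and the space under the mesenchymal slab is left empty
    so the germ can grow in depth.
    """

    AP_halflength: float = 6.5
    BL_halflength: float = 5.0
    bud_depth: float = 3.0
    spacing: float = 1.0
    suprabasal_layers: int = 2
    mesenchyme_depth: float = 2.0
    knot_width: int = 5
    dome_margin: float = 1.8

    def __post_init__(self):
        for name in ("AP_halflength", "BL_halflength", "bud_depth", "spacing",
                     "mesenchyme_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.suprabasal_layers < 1 or self.knot_width < 1:
            raise ValueError("need >= 1 suprabasal layer and knot cell")


_PRESETS = {
    # AP longer than BL, as in the mouse molar germ from early on
    "elongated": BudGeometry(AP_halflength=6.5, BL_halflength=5.0),
    # radially symmetric control (fang/canine-like mode)
    "radial": BudGeometry(AP_halflength=5.0, BL_halflength=5.0),
    # frontal-plane 2D model
    "2d-frontal": BudGeometry(AP_halflength=9.0, BL_halflength=9.0,
                              bud_depth=4.0, knot_width=3,
                              mesenchyme_depth=3.0),
}


def preset_geometry(name: str) -> BudGeometry:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


# ----------------------------------------------------------------------
# geometry helpers

_PLATEAU_FRAC = 0.45


def _dome_depth(x, y, wx, wy, depth):
    """Smooth bud profile z(x, y) <= 0: an elliptical flat-bottomed
    pocket (the knot sits on the plateau, with the flanking epithelium
    level with it at bud stage) whose walls climb over the same radial
    distance in every direction, as in a real bud whose wall slope does
    not depend on the germ's elongation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho = np.sqrt((x / wx) ** 2 + (y / wy) ** 2)
    # local semi-axis of the ellipse along this direction
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(rho > 0, np.sqrt(x**2 + y**2) / rho, wx)
    ramp_width = (1.0 - _PLATEAU_FRAC) * min(wx, wy)
    dist = (rho - _PLATEAU_FRAC) * local
    ramp = np.clip(dist / ramp_width, 0.0, 1.0)
    return -depth * np.cos(np.pi * ramp / 2.0) ** 2


def _sym_hex_grid(half_x, half_y, spacing):
    """Hexagonal-row lattice covering [-half_x, half_x] x [-half_y,
    half_y], exactly mirror-symmetric under x -> -x and y -> -y (so the
    built tissue carries no constructional left/right or
    anterior/posterior bias)."""
    dy = spacing * np.sqrt(3) / 2
    rows = int(np.floor(half_y / dy))
    pts = []
    for r in range(-rows, rows + 1):
        y = r * dy
        if abs(r) % 2:
            n = int(np.floor(half_x / spacing - 0.5))
            xs = [(k + 0.5) * spacing for k in range(n + 1)]
            xs = [-v for v in reversed(xs)] + xs
        else:
            n = int(np.floor(half_x / spacing))
            xs = [k * spacing for k in range(1, n + 1)]
            xs = [-v for v in reversed(xs)] + [0.0] + xs
        pts.extend((x, y) for x in xs)
    return np.array(pts)


def _sym_jitter(x, y, amp, dim):
    """Deterministic lattice-breaking jitter that respects both mirror
    symmetries (odd components flip with their coordinate)."""
    jx = amp * np.sin(2.7 * x) * np.cos(1.3 * y)
    jy = amp * np.cos(1.7 * x) * np.sin(2.3 * y)
    if dim == 2:
        return np.array([jx, jy])
    jz = amp * np.cos(2.1 * x) * np.cos(1.9 * y)
    return np.array([jx, jy, jz])


def _thin_surface_symmetric(xy, min_dist, height):
    """Greedy surface thinning that keeps whole mirror orbits.

    Points closer than min_dist/2 to an axis are snapped onto it so an
    orbit never conflicts with itself; orbits are admitted outward from
    the centre when all members clear ``min_dist`` (3D distance, with
    z = height(x, y)) from the points already kept."""
    xy = xy.copy()
    xy[np.abs(xy[:, 0]) < 0.5 * min_dist, 0] = 0.0
    xy[np.abs(xy[:, 1]) < 0.5 * min_dist, 1] = 0.0
    quad = xy[(xy[:, 0] >= 0) & (xy[:, 1] >= 0)]
    quad = np.unique(np.round(quad, 9), axis=0)
    order = np.lexsort((quad[:, 0], quad[:, 1], np.hypot(quad[:, 0], quad[:, 1])))
    kept: list[np.ndarray] = []
    # orbit rejection can leave holes where one mirror image is blocked;
    # follow-up passes at tighter radii fill them
    for radius in (min_dist, 0.88 * min_dist, 0.80 * min_dist):
        for i in order:
            x, y = quad[i]
            orbit_xy = {(x, y), (-x, y), (x, -y), (-x, -y)}
            cand = np.array([[ox, oy, float(height(ox, oy))]
                             for ox, oy in sorted(orbit_xy)])
            if kept:
                arr = np.asarray(kept)
                d = np.linalg.norm(arr[:, None, :] - cand[None, :, :], axis=2)
                if d.min() < radius:
                    continue
            kept.extend(cand)
    return np.asarray(kept)


# ----------------------------------------------------------------------

def build_bud_3d(geometry: BudGeometry | None = None,
                 mech: MechanicalDefaults | None = None,
                 adhesion: AdhesionTable | None = None,
                 relax_tolerance: float = 0.6,
                 relax_max_steps: int = 800,
                 seed: int = 0) -> SimulationState:
    """Bud-stage 3D initial condition.

    A dome-shaped epithelial monolayer (two-node cylinders, basal side
    facing the mesenchyme below) covers a suprabasal fill and sits above
    a mesenchymal slab.  The epithelial border ring and the uppermost
    suprabasal layer are fixed; the mid-line epithelial cells are
    flagged as the enamel knot.  The construction is exactly
    mirror-symmetric in both horizontal axes and fully deterministic
    (``seed`` is kept for interface stability), and the state is
    mechanically pre-relaxed so the residual force is below
    ``relax_tolerance``.
    """
    g = geometry or preset_geometry("elongated")
    m = mech or MechanicalDefaults()
    a = g.spacing
    wx = g.BL_halflength - g.dome_margin
    wy = g.AP_halflength - g.dome_margin
    half_eqs = 0.5 * m.p_EQS

    def height(x, y):
        return _dome_depth(x, y, wx, wy, g.bud_depth)

    # --- epithelium: symmetric uniform sampling of the pocket surface
    fine = _sym_hex_grid(g.BL_halflength, g.AP_halflength, 0.32 * a)
    surf = _thin_surface_symmetric(fine, 0.95 * a, height)
    if surf.shape[0] < g.knot_width + 4:
        raise ValueError("geometry too small to contain the enamel knot")
    # inward (upward) unit normals from the analytic surface gradient
    h = 1e-5
    gx = (height(surf[:, 0] + h, surf[:, 1])
          - height(surf[:, 0] - h, surf[:, 1])) / (2 * h)
    gy = (height(surf[:, 0], surf[:, 1] + h)
          - height(surf[:, 0], surf[:, 1] - h)) / (2 * h)
    normals = np.column_stack([-gx, -gy, np.ones(len(surf))])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    # knot: whole mirror orbits closest to the mid line
    rho = np.sqrt((surf[:, 0] / wx) ** 2 + (surf[:, 1] / wy) ** 2)
    is_knot = np.zeros(len(surf), dtype=bool)
    for value in np.unique(np.round(rho, 6)):
        group = np.round(rho, 6) == value
        is_knot |= group
        if is_knot.sum() >= g.knot_width:
            break
    border = (np.abs(surf[:, 0]) > g.BL_halflength - 1.1 * a) | (
        np.abs(surf[:, 1]) > g.AP_halflength - 1.1 * a)

    builder = StateBuilder(3, m, adhesion)
    for p, n, knot, fix in zip(surf, normals, is_knot, border):
        builder.add_epithelial(apical=p + half_eqs * n, basal=p - half_eqs * n,
                               fixed=bool(fix), knot=bool(knot))

    # --- suprabasal fill between the apical surface and the oral roof
    clearance = half_eqs + 0.95 * a
    z_top = clearance + 0.9 * a * (g.suprabasal_layers - 1)
    dz = 0.9 * a
    grid = _sym_hex_grid(g.BL_halflength - 0.5 * a, g.AP_halflength - 0.5 * a, a)
    zmid = height(grid[:, 0], grid[:, 1])
    for zl in np.arange(z_top, -g.bud_depth + clearance - 1e-9, -dz):
        fixed = zl > z_top - 0.5 * dz
        for x, y in grid[zl >= zmid + clearance]:
            jit = 0.0 if fixed else (1 + 0.3 * np.cos(2.9 * zl)) * _sym_jitter(x, y, 0.06, 3)
            builder.add_sphere(np.array([x, y, zl]) + jit, SUPRABASAL,
                               fixed=bool(fixed))

    # --- mesenchymal slab under the epithelium (space below left empty)
    z_bot = -g.bud_depth - g.mesenchyme_depth
    for zl in np.arange(-clearance, z_bot - 1e-9, -dz):
        for x, y in grid[zl <= zmid - clearance]:
            jit = (1 + 0.3 * np.cos(2.9 * zl)) * _sym_jitter(x, y, 0.06, 3)
            builder.add_sphere(np.array([x, y, zl]) + jit, MESENCHYME,
                               fixed=False)

    state = builder.build()
    mechanics.relax(state, force_tolerance=relax_tolerance,
                    max_steps=relax_max_steps)
    state.time = 0.0
    return state


def build_bud_2d(geometry: BudGeometry | None = None,
                 mech: MechanicalDefaults | None = None,
                 adhesion: AdhesionTable | None = None,
                 relax_tolerance: float = 0.6,
                 relax_max_steps: int = 800,
                 seed: int = 0) -> SimulationState:
    """Bud-stage initial condition restricted to a frontal plane.

    x is the bucco-lingual axis, y the depth axis (0 = oral surface,
    negative = into the jaw).  The epithelium is a chain of two-node
    cells along a U-shaped mid-curve sampled symmetrically about the mid
    line; the chain's end cells are fixed.  Fully deterministic and
    mirror-symmetric, like the 3D constructor.
    """
    g = geometry or preset_geometry("2d-frontal")
    m = mech or MechanicalDefaults()
    a = g.spacing
    w = g.BL_halflength - 1.5 * g.dome_margin
    half_eqs = 0.5 * m.p_EQS

    def y_mid(x):
        return _dome_depth(x, 0.0, w, 1.0, g.bud_depth)

    # arclength-uniform sampling of the mid-curve, centred on x = 0
    xs = np.linspace(-g.BL_halflength, g.BL_halflength, 4001)
    ys = y_mid(xs)
    seg = np.hypot(np.diff(xs), np.diff(ys))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    half_n = int(np.floor(0.5 * s[-1] / a))
    targets = 0.5 * s[-1] + a * np.arange(-half_n, half_n + 1)
    n_cells = targets.size
    px = np.interp(targets, s, xs)
    py = np.interp(targets, s, ys)
    px[half_n] = 0.0  # exact mid-line cell
    # inward normals (positive-y on the flat part)
    tx = np.gradient(px)
    ty = np.gradient(py)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm

    half_k = g.knot_width // 2
    knot_range = range(half_n - half_k, half_n + half_k + 1)

    builder = StateBuilder(2, m, adhesion)
    for i in range(n_cells):
        mid = np.array([px[i], py[i]])
        nrm = np.array([nx[i], ny[i]])
        fixed = i < 2 or i >= n_cells - 2
        builder.add_epithelial(apical=mid + half_eqs * nrm,
                               basal=mid - half_eqs * nrm,
                               fixed=fixed, knot=i in knot_range)

    clearance = half_eqs + 0.95 * a
    dz = 0.9 * a
    y_top = clearance + 0.9 * a * (g.suprabasal_layers - 1)

    def sym_xs(level_index):
        if level_index % 2:
            n = int(np.floor((g.BL_halflength - 0.5 * a) / a - 0.5))
            vals = [(k + 0.5) * a for k in range(n + 1)]
            return [-v for v in reversed(vals)] + vals
        n = int(np.floor((g.BL_halflength - 0.5 * a) / a))
        vals = [k * a for k in range(1, n + 1)]
        return [-v for v in reversed(vals)] + [0.0] + vals

    for il, yl in enumerate(np.arange(y_top, -g.bud_depth + clearance - 1e-9, -dz)):
        fixed = yl > y_top - 0.5 * dz
        for x in sym_xs(il):
            if yl >= y_mid(x) + clearance:
                jit = 0.0 if fixed else _sym_jitter(x, yl, 0.06, 2)
                builder.add_sphere(np.array([x, yl]) + jit, SUPRABASAL,
                                   fixed=bool(fixed))

    y_bot = -g.bud_depth - g.mesenchyme_depth
    for il, yl in enumerate(np.arange(-clearance, y_bot - 1e-9, -dz)):
        for x in sym_xs(il):
            if yl <= y_mid(x) - clearance:
                builder.add_sphere(
                    np.array([x, yl]) + _sym_jitter(x, yl, 0.06, 2),
                    MESENCHYME, fixed=False)

    state = builder.build()
    mechanics.relax(state, force_tolerance=relax_tolerance,
                    max_steps=relax_max_steps)
    state.time = 0.0
    return state


def expected_2d_epithelial_count(geometry: BudGeometry) -> int:
    """Cell count the 2D constructor will produce (arclength arithmetic)."""
    g = geometry
    w = g.BL_halflength - 1.5 * g.dome_margin
    xs = np.linspace(-g.BL_halflength, g.BL_halflength, 4001)
    ys = _dome_depth(xs, 0.0, w, 1.0, g.bud_depth)
    s = np.hypot(np.diff(xs), np.diff(ys)).sum()
    return 2 * int(np.floor(0.5 * s / g.spacing)) + 1


# ----------------------------------------------------------------------
# reference growth curves

@dataclass
class ReferenceCurves:
    """Epithelial perimeter and suprabasal area over percent time, in a
    declared reference unit of length (unit-free comparisons only)."""

    percent_time: np.ndarray
    perimeter: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        self.percent_time = np.asarray(self.percent_time, float)
        self.perimeter = np.asarray(self.perimeter, float)
        self.area = np.asarray(self.area, float)
        if np.any(np.diff(self.percent_time) <= 0):
            raise ValueError("percent time must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "percent_time": self.percent_time,
            "perimeter": self.perimeter,
            "area": self.area,
        })

    @classmethod
    def from_frame(cls, df):
        return cls(df["percent_time"].to_numpy(), df["perimeter"].to_numpy(),
                   df["area"].to_numpy())


@dataclass(frozen=True)
class CurveShape:
    """Fold changes over the bud-to-cap span: the epithelial perimeter
    rises faster than the suprabasal area (the regime that forces the
    epithelium to fold)."""

    perimeter0: float = 1.0
    area0: float = 1.0
    perimeter_fold: float = 4.0
    area_fold: float = 2.0


def synth_reference_curves(shape: CurveShape | None = None,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | int | None = None,
                           n_points: int = 25) -> ReferenceCurves:
    """Exponential-like reference curves with multiplicative lognormal
    noise of the given sd (0 = the smooth noise-free core)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    shape = shape or CurveShape()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tau = np.linspace(0.0, 1.0, n_points)
    perim = shape.perimeter0 * shape.perimeter_fold**tau
    area = shape.area0 * shape.area_fold**tau
    if noise_sd > 0:
        perim = perim * np.exp(rng.normal(0.0, noise_sd, n_points))
        area = area * np.exp(rng.normal(0.0, noise_sd, n_points))
    return ReferenceCurves(100.0 * tau, perim, area)


# ----------------------------------------------------------------------
# landmark series emulating the separation-assay digitization

_BASE_SHAPE = np.array([
    [-3.0, 0.0],   # 1: left junction, outer enamel epithelium / oral epithelium
    [-1.5, -2.6],  # 2: left cervical-loop maximum of curvature
    [1.5, -2.6],   # 3: right cervical-loop maximum of curvature
    [3.0, 0.0],    # 4: right junction
])

# opening mode: loop tips swing outward and up as the growth angle opens
_OPENING_MODE = np.array([
    [0.0, 0.0],
    [-1.1, 1.6],
    [1.1, 1.6],
    [0.0, 0.0],
])


def synth_landmark_series(n_specimens: int = 3, n_frames: int = 120,
                          deformation_amplitude: float = 1.0,
                          digitizing_sd: float = 0.02,
                          rng: np.random.Generator | int | None = None,
                          n_replicates: int = 2,
                          specimen_scatter: float = 0.25) -> list[LandmarkSeries]:
    """Per-specimen landmark series along one deformation mode
    (cervical-loop opening), digitized ``n_replicates`` times with
    isotropic noise of sd ``digitizing_sd``.

    Each specimen starts from the base 4-landmark shape perturbed by a
    specimen-specific offset of scale ``specimen_scatter`` (so a
    specimen effect exists for the ANOVA) and interpolates linearly
    toward the opened shape over the frames.
    """
    if n_frames < 2:
        raise ValueError("need n_frames >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[LandmarkSeries] = []
    for s in range(n_specimens):
        base = _BASE_SHAPE + specimen_scatter * rng.normal(size=_BASE_SHAPE.shape)
        truth = [
            base + deformation_amplitude * (f / (n_frames - 1)) * _OPENING_MODE
            for f in range(n_frames)
        ]
        for rep in range(n_replicates):
            frames = [
                LandmarkConfiguration(
                    t + rng.normal(0.0, digitizing_sd, size=t.shape)
                    if digitizing_sd > 0 else t.copy(),
                    specimen=f"germ{s}", frame=f, replicate=rep)
                for f, t in enumerate(truth)
            ]
            out.append(LandmarkSeries(frames, specimen=f"germ{s}", replicate=rep))
    return out
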
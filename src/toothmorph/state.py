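"""Core data containers for the tooth-germ simulation.

The tissue is represented as a cloud of mechanical particles ("nodes").
Mesenchymal and suprabasal cells are single spherical nodes; epithelial
cells are two-node cylinders (one apical, one basal node joined by an
elastic spring).  All per-node mechanical parameters and per-cell
biological bookkeeping live in flat numpy arrays inside a single
:class:`SimulationState`, the object every stage of the pipeline
transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# node roles
SPHERE = 0
APICAL = 1
BASAL = 2
ROLE_NAMES = ("sphere", "epithelial_apical", "epithelial_basal")

# tissues (also index the adhesion-molecule axis: one molecule per tissue)
EPITHELIUM = 0
SUPRABASAL = 1
MESENCHYME = 2
TISSUE_NAMES = ("epithelium", "suprabasal", "mesenchyme")
N_MOLECULES = 3


@dataclass(frozen=True)
class MechanicalDefaults:
    """Per-node mechanical parameters, in model length units (one cell
    diameter = 1) and hours.

    p_REC : repulsion (incompressibility) coefficient
    p_EQD : equilibrium radius (half the rest contact distance)
    p_ADD : maximum interaction radius (half the contact cut-off)
    p_HOO : apical-basal spring stiffness contribution
    p_EST : radial epithelial bending coefficient
    p_ERP : rotational epithelial bending coefficient
    p_EQS : equilibrium apical-basal spring length
    """

    p_REC: float = 5.0
    p_EQD: float = 0.5
    p_ADD: float = 0.7
    p_HOO: float = 10.0
    p_EST: float = 3.0
    p_ERP: float = 3.0
    p_EQS: float = 1.0

    def __post_init__(self) -> None:
        if self.p_EQD <= 0:
            raise ValueError("p_EQD must be > 0")
        if self.p_ADD < self.p_EQD:
            raise ValueError("p_ADD must be >= p_EQD")
        for name in ("p_REC", "p_HOO", "p_EST", "p_ERP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p_EQS <= 0:
            raise ValueError("p_EQS must be > 0")


class AdhesionTable:
    """Symmetric matrix of adhesive affinities b_mn between adhesion
    molecules.  In the tooth model molecules are tissue specific, so the
    matrix reduces to the six entries b_EE, b_ES, b_EM, b_SS, b_SM, b_MM.
    """

    def __init__(self, b: np.ndarray | None = None):
        if b is None:
            b = np.ones((N_MOLECULES, N_MOLECULES))
        b = np.asarray(b, dtype=float)
        if b.shape != (N_MOLECULES, N_MOLECULES):
            raise ValueError(f"adhesion matrix must be {N_MOLECULES}x{N_MOLECULES}")
        if not np.allclose(b, b.T):
            raise ValueError("adhesion matrix must be symmetric")
        if np.any(b < 0):
            raise ValueError("adhesive affinities must be >= 0")
        self.b = b

    @classmethod
    def from_pairs(cls, b_EE=1.0, b_ES=1.0, b_EM=1.0, b_SS=1.0, b_SM=1.0, b_MM=1.0):
        b = np.array(
            [
                [b_EE, b_ES, b_EM],
                [b_ES, b_SS, b_SM],
                [b_EM, b_SM, b_MM],
            ]
        )
        return cls(b)

    def with_pair(self, tissue_a: int, tissue_b: int, value: float) -> "AdhesionTable":
        b = self.b.copy()
        b[tissue_a, tissue_b] = b[tissue_b, tissue_a] = value
        return AdhesionTable(b)

    def __getitem__(self, key):
        return self.b[key]

    def __eq__(self, other):
        return isinstance(other, AdhesionTable) and np.array_equal(self.b, other.b)

    def __repr__(self):
        return f"AdhesionTable({self.b.tolist()})"


@dataclass
class NodeState:
    """A single mechanical particle (scalar view; the simulation itself
    uses the flat arrays in :class:`SimulationState`)."""

    id: int
    position: np.ndarray
    role: int = SPHERE
    cell_id: int = 0
    fixed: bool = False
    p_REC: float = 5.0
    p_EQD: float = 0.5
    p_ADD: float = 0.7
    p_HOO: float = 10.0
    p_EST: float = 3.0
    p_ERP: float = 3.0
    expression: np.ndarray = field(default_factory=lambda: np.zeros(N_MOLECULES))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if self.p_EQD <= 0 or self.p_ADD < self.p_EQD:
            raise ValueError("need p_ADD >= p_EQD > 0")
        if min(self.p_REC, self.p_HOO, self.p_EST, self.p_ERP) < 0:
            raise ValueError("mechanical coefficients must be >= 0")
        if np.any(self.expression < 0):
            raise ValueError("expression levels must be >= 0")


@dataclass
class SimulationState:
    """All nodes + cells + adhesion table + cell-cycle clock.

    Node arrays (length N): ``positions`` is (N, dim) with dim 2 (planar
    frontal-section mode) or 3; ``role``, ``node_cell``, ``fixed`` and the
    six mechanical parameter arrays follow; ``expression`` is (N, 3) with
    one tissue-specific adhesion molecule per tissue.

    Cell arrays (length C): ``cell_tissue``, ``cell_knot`` (enamel-knot
    flag), ``cell_phase`` (cell-cycle progression P_PHA in [0, 1]),
    ``cell_nodes`` (C, 2) node indices with column 1 == -1 for spheres,
    and ``cell_EQS`` (spring rest length, NaN for spheres).
    """

    positions: np.ndarray
    role: np.ndarray
    node_cell: np.ndarray
    fixed: np.ndarray
    p_REC: np.ndarray
    p_EQD: np.ndarray
    p_ADD: np.ndarray
    p_HOO: np.ndarray
    p_EST: np.ndarray
    p_ERP: np.ndarray
    expression: np.ndarray
    cell_tissue: np.ndarray
    cell_knot: np.ndarray
    cell_phase: np.ndarray
    cell_nodes: np.ndarray
    cell_EQS: np.ndarray
    adhesion: AdhesionTable = field(default_factory=AdhesionTable)
    time: float = 0.0

    # ------------------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cell_tissue.shape[0]

    @property
    def epithelial_cells(self) -> np.ndarray:
        return np.flatnonzero(self.cell_tissue == EPITHELIUM)

    def node_tissue(self) -> np.ndarray:
        """Tissue label of every node (via its cell)."""
        return self.cell_tissue[self.node_cell]

    def cell_centroids(self) -> np.ndarray:
        """(C, dim) centroid of each cell (node position for spheres,
        midpoint for epithelial cylinders)."""
        out = self.positions[self.cell_nodes[:, 0]].copy()
        two = self.cell_nodes[:, 1] >= 0
        out[two] = 0.5 * (out[two] + self.positions[self.cell_nodes[two, 1]])
        return out

    def node(self, i: int) -> NodeState:
        return NodeState(
            id=i,
            position=self.positions[i].copy(),
            role=int(self.role[i]),
            cell_id=int(self.node_cell[i]),
            fixed=bool(self.fixed[i]),
            p_REC=float(self.p_REC[i]),
            p_EQD=float(self.p_EQD[i]),
            p_ADD=float(self.p_ADD[i]),
            p_HOO=float(self.p_HOO[i]),
            p_EST=float(self.p_EST[i]),
            p_ERP=float(self.p_ERP[i]),
            expression=self.expression[i].copy(),
        )

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            role=self.role.copy(),
            node_cell=self.node_cell.copy(),
            fixed=self.fixed.copy(),
            p_REC=self.p_REC.copy(),
            p_EQD=self.p_EQD.copy(),
            p_ADD=self.p_ADD.copy(),
            p_HOO=self.p_HOO.copy(),
            p_EST=self.p_EST.copy(),
            p_ERP=self.p_ERP.copy(),
            expression=self.expression.copy(),
            cell_tissue=self.cell_tissue.copy(),
            cell_knot=self.cell_knot.copy(),
            cell_phase=self.cell_phase.copy(),
            cell_nodes=self.cell_nodes.copy(),
            cell_EQS=self.cell_EQS.copy(),
            adhesion=AdhesionTable(self.adhesion.b.copy()),
            time=self.time,
        )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on breach."""
        n, c = self.n_nodes, self.n_cells
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite node positions")
        if np.any(self.p_EQD <= 0) or np.any(self.p_ADD < self.p_EQD):
            raise ValueError("need p_ADD >= p_EQD > 0 for every node")
        for name in ("p_REC", "p_HOO", "p_EST", "p_ERP"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be >= 0")
        if np.any(self.expression < 0):
            raise ValueError("expression levels must be >= 0")
        if np.any((self.node_cell < 0) | (self.node_cell >= c)):
            raise ValueError("node_cell out of range")
        sphere_cells = self.cell_nodes[:, 1] < 0
        if np.any(self.cell_tissue[sphere_cells] == EPITHELIUM):
            raise ValueError("epithelial cells must have two nodes")
        if np.any(self.cell_tissue[~sphere_cells] != EPITHELIUM):
            raise ValueError("sphere cells must have one node")
        two = ~sphere_cells
        if np.any(self.role[self.cell_nodes[two, 0]] != APICAL) or np.any(
            self.role[self.cell_nodes[two, 1]] != BASAL
        ):
            raise ValueError("epithelial cells must pair one apical and one basal node")
        if np.any(self.cell_EQS[two] <= 0):
            raise ValueError("spring rest length must be > 0")
        if np.any(self.cell_knot & (self.cell_tissue != EPITHELIUM)):
            raise ValueError("enamel-knot cells must be epithelial")
        if np.any((self.cell_phase < 0) | (self.cell_phase > 1)):
            raise ValueError("P_PHA must lie in [0, 1]")
        # node -> cell back references consistent
        owner = np.full(n, -1, dtype=int)
        owner[self.cell_nodes[:, 0]] = np.arange(c)
        owner[self.cell_nodes[two, 1]] = np.flatnonzero(two)
        if np.any(owner != self.node_cell):
            raise ValueError("cell_nodes inconsistent with node_cell")


class StateBuilder:
    """Incremental constructor used by the synthetic-geometry module."""

    def __init__(self, dim: int, mech: MechanicalDefaults | None = None,
                 adhesion: AdhesionTable | None = None):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.dim = dim
        self.mech = mech or MechanicalDefaults()
        self.adhesion = adhesion or AdhesionTable()
        self._pos: list[np.ndarray] = []
        self._role: list[int] = []
        self._cell_of_node: list[int] = []
        self._fixed: list[bool] = []
        self._tissue: list[int] = []
        self._knot: list[bool] = []
        self._cell_nodes: list[tuple[int, int]] = []

    def add_sphere(self, position, tissue: int, fixed: bool = False) -> int:
        cid = len(self._tissue)
        nid = len(self._pos)
        self._pos.append(np.asarray(position, dtype=float))
        self._role.append(SPHERE)
        self._cell_of_node.append(cid)
        self._fixed.append(fixed)
        self._tissue.append(tissue)
        self._knot.append(False)
        self._cell_nodes.append((nid, -1))
        return cid

    def add_epithelial(self, apical, basal, fixed: bool = False,
                       knot: bool = False) -> int:
        cid = len(self._tissue)
        na, nb = len(self._pos), len(self._pos) + 1
        self._pos.append(np.asarray(apical, dtype=float))
        self._pos.append(np.asarray(basal, dtype=float))
        self._role.extend([APICAL, BASAL])
        self._cell_of_node.extend([cid, cid])
        self._fixed.extend([fixed, fixed])
        self._tissue.append(EPITHELIUM)
        self._knot.append(knot)
        self._cell_nodes.append((na, nb))
        return cid

    def build(self, time: float = 0.0) -> SimulationState:
        n = len(self._pos)
        if n == 0:
            raise ValueError("no nodes added")
        m = self.mech
        tissue = np.asarray(self._tissue, dtype=np.int8)
        node_cell = np.asarray(self._cell_of_node, dtype=np.int64)
        expression = np.zeros((n, N_MOLECULES))
        expression[np.arange(n), tissue[node_cell]] = 1.0
        cell_nodes = np.asarray(self._cell_nodes, dtype=np.int64)
        cell_EQS = np.where(cell_nodes[:, 1] >= 0, m.p_EQS, np.nan)
        state = SimulationState(
            positions=np.asarray(self._pos, dtype=float).reshape(n, self.dim),
            role=np.asarray(self._role, dtype=np.int8),
            node_cell=node_cell,
            fixed=np.asarray(self._fixed, dtype=bool),
            p_REC=np.full(n, m.p_REC),
            p_EQD=np.full(n, m.p_EQD),
            p_ADD=np.full(n, m.p_ADD),
            p_HOO=np.full(n, m.p_HOO),
            p_EST=np.full(n, m.p_EST),
            p_ERP=np.full(n, m.p_ERP),
            expression=expression,
            cell_tissue=tissue,
            cell_knot=np.asarray(self._knot, dtype=bool),
            cell_phase=np.zeros(len(self._tissue)),
            cell_nodes=cell_nodes,
            cell_EQS=cell_EQS,
            adhesion=self.adhesion,
            time=time,
        )
        state.validate()
        return state
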
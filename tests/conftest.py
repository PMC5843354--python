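import pytest

from toothmorph.state import MESENCHYME, NodeState, StateBuilder


@pytest.fixture
def two_spheres():
    """Two adhering mesenchymal spheres 1.2 apart (rest distance 1.0)."""
    b = StateBuilder(3)
    b.add_sphere([0.0, 0.0, 0.0], MESENCHYME)
    b.add_sphere([1.2, 0.0, 0.0], MESENCHYME)
    return b.build()


@pytest.fixture
def flat_sheet_2d():
    """Planar epithelial chain at rest spacing: an exact fixed point."""
    b = StateBuilder(2)
    for k in range(12):
        b.add_epithelial(apical=[float(k), 0.5], basal=[float(k), -0.5])
    return b.build()


@pytest.fixture
def flat_sheet_3d():
    """Regular 3D epithelial sheet, cylinders normal to the plane,
    in-plane square lattice at the rest distance."""
    b = StateBuilder(3)
    for i in range(6):
        for j in range(6):
            b.add_epithelial(apical=[float(i), float(j), 0.5],
                             basal=[float(i), float(j), -0.5])
    return b.build()


def random_node(rng, dim=3, role=0, expression=None):
    eqd = rng.uniform(0.3, 0.8)
    expr = expression if expression is not None else rng.uniform(0, 2, 3)
    return NodeState(
        id=0,
        position=rng.uniform(-2, 2, dim),
        role=role,
        p_REC=rng.uniform(0, 10),
        p_EQD=eqd,
        p_ADD=eqd + rng.uniform(0.05, 0.5),
        p_HOO=rng.uniform(0, 10),
        p_EST=rng.uniform(0, 5),
        p_ERP=rng.uniform(0, 5),
        expression=expr,
    )
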
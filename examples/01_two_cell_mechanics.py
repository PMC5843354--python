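"""Contact mechanics of a node pair.

Builds two adhering mesenchymal cells slightly apart, prints the signed
contact modulus across the force law's three branches, and relaxes the
pair to its analytic rest distance (the sum of the equilibrium radii).
"""

import numpy as np

from toothmorph import AdhesionTable, relax
from toothmorph.mechanics import pair_interaction_force
from toothmorph.state import MESENCHYME, NodeState, StateBuilder

adhesion = AdhesionTable.from_pairs(b_MM=5.0)
a = NodeState(0, [0.0, 0.0, 0.0], expression=[0, 0, 1])

print("distance  modulus (positive = attraction)")
for d in (0.8, 1.0, 1.2, 1.45):
    b = NodeState(1, [d, 0.0, 0.0], expression=[0, 0, 1])
    print(f"{d:8.2f}  {pair_interaction_force(a, b, adhesion):+.3f}")

builder = StateBuilder(3, adhesion=adhesion)
builder.add_sphere([0, 0, 0], MESENCHYME)
builder.add_sphere([1.3, 0, 0], MESENCHYME)
state = builder.build()
result = relax(state, force_tolerance=1e-8, dt=0.01, max_steps=50_000)
d = np.linalg.norm(state.positions[1] - state.positions[0])
print(f"\nrelaxed in {result.steps} steps; distance {d:.8f} "
      "(rest distance is 1.0 = p_EQD_i + p_EQD_j)")
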
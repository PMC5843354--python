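"""In-silico epithelium-mesenchyme separation.

Grows a deep cap-stage 2D germ (42 h), then sets the epithelial-mesenchymal adhesion
to zero and relaxes to equilibrium, mimicking enzymatic separation of
the tissues.  Prints the growth angle (tracked at the material loop
tips) and the follicular-mesenchyme width before and after, plus the
PCA of the 4-landmark frames recorded during the relaxation.
"""

import numpy as np

from toothmorph import (
    AdhesionTable,
    GrowthConfig,
    MechanicalDefaults,
    RunConfig,
    build_bud_2d,
    gpa,
    run_simulation,
    separation_assay,
    shape_pca,
)

mech = MechanicalDefaults(p_EST=1.0, p_ERP=1.0)
adhesion = AdhesionTable.from_pairs(b_EM=5.0, b_MM=5.0, b_SS=5.0)
growth = GrowthConfig(hypothesis="III", s_epi=0.055, s_sup=0.033, s_mes=0.245,
                      signal_threshold=0.3, signal_length_scale=1.5)

state = build_bud_2d(None, mech, adhesion, seed=1)
cap = run_simulation(state, RunConfig(growth=growth, total_time=42.0, seed=9,
                                      snapshot_interval=42.0))[-1]
result = separation_assay(cap, force_tolerance=0.08, max_steps=15000)

print(f"growth angle:           {result.angle_before:6.1f} -> "
      f"{result.angle_after:6.1f} deg")
print(f"follicular mesenchyme:  {result.width_before:6.2f} -> "
      f"{result.width_after:6.2f}")
print("Cutting the epithelial-mesenchymal adhesion makes the loop angle "
      "stop\nclosing and edge upward, while the follicular mesenchyme "
      "recoils sharply\ntowards the mid line -- the dominant signature "
      "of the assay at this scale.")

pca = shape_pca(gpa(result.landmarks.configurations()))
scores = pca.scores[:, 0]
corr = np.corrcoef(np.arange(scores.size), scores)[0, 1]
print(f"landmark PCA: PC1 carries {100 * pca.variance_fractions[0]:.0f}% of "
      f"shape variance; PC1-vs-time correlation {corr:+.2f}")
print("PC1 tracks the opening of the loops through the relaxation frames.")
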
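"""Landmark morphometrics on a synthetic digitization design.

Generates the 3-specimens x 120-frames x 2-replicates landmark design
(cervical-loop opening mode plus digitizing noise), writes/reads it as
TPS, runs GPA + shape PCA, and quantifies digitizing error with a
Procrustes ANOVA.
"""

import tempfile
from pathlib import Path

from toothmorph import gpa, procrustes_anova, read_tps, shape_pca, write_tps
from toothmorph.synthetic import synth_landmark_series

series = synth_landmark_series(n_specimens=3, n_frames=120, digitizing_sd=0.02,
                               rng=42)
configs = [c for s in series for c in s.configurations()]
print(f"{len(configs)} landmark configurations "
      "(3 specimens x 120 frames x 2 digitizing replicates)")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "series.tps"
    write_tps(path, configs)
    configs = read_tps(path)

result = gpa(configs)
pca = shape_pca(result)
print(f"GPA consensus reached; PC1 explains "
      f"{100 * pca.variance_fractions[0]:.1f}% of shape variance "
      "(the loop-opening mode)")

anova = procrustes_anova(configs, n_permutations=999, seed=0)
print(anova.shape_table.round(6))
print(f"specimen effect: F = {anova.f_shape:.1f}, permutation "
      f"P = {anova.p_shape_perm:.4f} -> digitizing error is negligible "
      "next to real shape differences")
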
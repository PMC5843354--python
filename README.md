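# toothmorph

A cell-based biomechanical model of early tooth morphogenesis — the
bud-to-cap transition of the mammalian molar germ — together with the
in-silico experiments used to probe it and landmark-based Procrustes
morphometrics.

## Who this is for

Developmental biologists and biomechanics modellers who want a small,
fully scriptable sandbox for epithelial folding driven by **differential
tissue growth** and **differential cell adhesion**, with no external
data dependencies: every input (bud-stage geometries, reference growth
curves, landmark digitization series) is generated by the package.

## The model

The tooth germ is three tissues made of mechanical particles ("nodes"):

* **enamel epithelium** — two-node cylinders (apical + basal node joined
  by an elastic spring), forming a monolayer;
* **suprabasal layer** and **mesenchyme** — single spherical nodes;
* a non-dividing **enamel knot** at the epithelial mid line that
  secretes a diffusible growth signal.

Nodes move by overdamped first-order dynamics, `dr_i/dt = Σ_j f_A(d_ij) u_ij`,
where the pairwise modulus is linear repulsion below the rest distance
`EQDsum = p_EQD_i + p_EQD_j`, linear adhesion with strength
`k_ADH = Σ_mn g_im g_jn b_mn` between the rest distance and the cut-off
`ADDsum`, and zero beyond.  The symmetric tissue-affinity matrix `b`
(entries `b_EE, b_ES, b_EM, b_SS, b_SM, b_MM`) encodes the differential
adhesion hypothesis.  Epithelial nodes additionally feel the
apical-basal spring and two bending terms (a radial term levelling
neighbouring cylinders, a rotational term keeping cylinders normal to
the sheet), which make the epithelium behave as an elastic monolayer.

Cells carry a cycle phase `P_PHA ∈ [0, 1]` advancing at the
tissue-specific rate `s` (h⁻¹, the inverse cycle length); at 1 the cell
divides, placing a daughter at a small random offset.  Three
proliferation hypotheses are supported: uniform per-tissue rates (I),
knot-signal-gated proliferation everywhere (II), and uniform
epithelium/suprabasal with signal-gated mesenchyme (III).

On top of the simulator sit the study's in-silico experiments: growth
and adhesion parameter screens, growth-angle and loop-depth
measurements, Delaunay growth curves with an RMSE fit to reference
curves, cell-trajectory tracking and tip retention, the
epithelium–mesenchyme separation assay, per-contact stress maps, the
closed-form geometric model of anterior-posterior vs bucco-lingual loop
asymmetry, and GPA / shape-PCA / Procrustes-ANOVA morphometrics with
TPS I/O.

## Worked example

`examples/02_bud_to_cap_2d.py` grows the frontal-plane bud for 36 h
under hypothesis III with strong epithelial-mesenchymal and mesenchymal
homotypic adhesion:

```
time (h)  cells  growth angle (deg)
       0    177     179.6
       6    190     176.5
      12    215     171.9
      18    278     166.9
      24    341     162.8
      30    421     152.1
      36    556     139.6
```

The growth angle is measured at the enamel knot between the two
cervical-loop tips in the frontal plane: ~180° means the bud walls point
sideways; the steady fall towards ~140° is the cap forming as the loops
grow down around the dental papilla.  The other examples cover the contact
force law, the separation assay, the morphometrics pipeline and the
geometric asymmetry model, each printing and explaining its numbers.

A thin CLI mirrors the library (`toothmorph init/run/screen/measure/
separate/fit/track/stress/geom/synth/gpa/pca/anova`); every stochastic
subcommand requires an explicit `--seed`.

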
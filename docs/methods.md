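# Methods

## Model

The tooth germ is represented as a cloud of mechanical particles
("nodes") in 3D, or in a frontal 2D plane.  Mesenchymal and suprabasal
cells are single spherical nodes; epithelial cells are two-node
cylinders whose apical and basal nodes are joined by an elastic spring,
so the epithelium is a discrete monolayer with sidedness (apical facing
the suprabasal layer, basal facing the mesenchyme).

Node motion is overdamped and first order — velocity equals force with
unit mobility; there is no inertia and no thermal noise, so the
dynamics are fully deterministic given an initial state.  Forces are:

* **Contact forces** between neighbouring nodes (centre distance within
  the pairwise cut-off `ADDsum = p_ADD_i + p_ADD_j`).  The signed
  modulus is linear repulsion `(p_REC_i + p_REC_j)(d − EQDsum)` below
  the rest distance `EQDsum = p_EQD_i + p_EQD_j`, linear adhesion
  `k_ADH (d − EQDsum)` between rest distance and cut-off, and zero
  beyond.  The adhesion slope `k_ADH = Σ_mn g_im g_jn b_mn` couples the
  nodes' adhesion-molecule amounts through the symmetric affinity
  matrix `b`; the tooth model expresses one molecule per tissue, so
  `k_ADH` reduces to the tissue-pair entries `b_EE … b_MM`.  Both
  branches vanish at the rest distance; the adhesive branch drops
  discontinuously to zero at the cut-off (cells losing contact).
* **Apical-basal spring** per epithelial cell, modulus
  `(p_HOO_a + p_HOO_b)(d − p_EQS)` along the cylinder axis.
* **Epithelial bending**, evaluated over same-face neighbour pairs
  (apical with apical, basal with basal): a radial term
  `k_EST (m·c/|m|) m̂` with `m` the sum of the two cylinder axes and `c`
  the inter-node vector, levelling neighbouring cylinders; and a
  rotational term `p_ERP (s·c/|s|) ĉ`, applied one-sidedly per node
  with its own coefficient, tilting each cylinder towards the local
  sheet normal.  Cylinder axes are taken from each node to its partner,
  which makes both terms restoring; both vanish exactly at 90°.

A regular planar sheet at rest spacing is an exact fixed point of the
full force field (residual < 1e−9), and all contact/spring terms obey
action-reaction to machine precision.

## Cell dynamics

Each cell advances a cycle phase `P_PHA ∈ [0, 1]` at the tissue rate
`s_epi`, `s_sup` or `s_mes` (h⁻¹ = inverse cycle length); at 1 it
divides and both daughters restart at 0.  Daughters inherit tissue,
mechanical parameters and expression, and are placed at a random offset
of at most ε = 0.25 cell diameters (spheres: random direction;
epithelial cells: a new cylinder offset within the local tangent plane
with the parent's axis copied, preserving the monolayer).  Enamel-knot
cells never divide and keep their identity.

The knot secretes a diffusible signal modelled as a quasi-steady
exponential kernel, `c(x) = Σ_sources exp(−dist/λ)`: the model's logic
only uses the position of the `c = θ` level set, so explicit
production/diffusion/decay dynamics are not resolved.  Defaults
`λ = 2.5`, `θ = 0.25` (the bud builders' screens use `λ = 1.5`,
`θ = 0.3`) put the supra-threshold region over the dental — not
follicular — mesenchyme of the default bud.  The three proliferation
hypotheses gate eligibility: (I) everyone divides at their tissue rate;
(II) only cells with `c ≥ θ` divide; (III) epithelium and suprabasal as
in I, mesenchyme as in II.

## Numerics

Integration is forward Euler with a per-step displacement cap of
0.1 × min `p_EQD`, which keeps the stiff repulsive branch stable; the
default step is `dt = 0.01` h-equivalents (above ~0.02 the
spring/repulsion stiffness of dense 3D packings makes capped Euler
oscillate instead of converge).  During growth runs, mechanics are
treated quasi-statically: each growth step of `dt_growth = 0.25` h is
followed by 30 capped Euler sub-steps whose pseudo-time does not
advance the biological clock.  Relaxation (`relax`) iterates until the
maximum per-node force drops below a tolerance, with a step budget and
convergence flag.  Coincident nodes (which division placement can
create) receive a deterministic pseudo-random contact direction.

Mechanical defaults: `p_REC = 5`, `p_EQD = 0.5`, `p_ADD = 0.7`
(cell diameter 1, contact cut-off 1.4), `p_HOO = 10`, `p_EQS = 1`,
`p_EST = p_ERP = 3` (the morphogenesis experiments use 1–2: lower
bending stiffness lets the loops fold, higher values smooth the fast
hypothesis-I regime).  All are per-node arrays and per-run
configurable.

## Synthetic inputs

**Bud geometries.**  The 3D initial condition is an elliptical
flat-bottomed epithelial pocket (the knot sits on the plateau, flanked
level by the adjacent epithelium) whose walls climb over the same
radial distance in every direction, over a suprabasal fill up to a
fixed oral roof and above a mesenchymal slab with empty space below, so
the germ can grow in depth.  The epithelial border ring and the top
suprabasal layer are fixed in space.  Construction is exactly
mirror-symmetric in both horizontal axes — symmetric lattices,
orbit-preserving surface thinning with axis snapping, and a
deterministic parity-respecting jitter — because constructional
left/right bias otherwise swamps the anterior-posterior vs
bucco-lingual comparisons.  Presets: `elongated` (AP half-length 6.5,
BL 5.0), `radial` (5.0/5.0), `2d-frontal` (frontal-plane restriction,
U-shaped epithelial chain sampled symmetrically by arclength).
Default sizes target ~10³ cells in 3D and ~200 in 2D so full runs
finish in minutes on one core.

**Reference growth curves** stand in for time-lapse measurements
digitized from video: exponential-like curves over percent
developmental time in which the epithelial perimeter rises faster
(4-fold) than the suprabasal area (2-fold) — the regime that forces
epithelial folding and that the fitting machinery must discriminate —
with optional multiplicative lognormal noise.

**Landmark series** emulate the separation-assay digitization design:
per specimen, a base 4-landmark cap outline (two
epithelium/oral-epithelium junctions, two cervical-loop curvature
maxima) interpolates toward an "opened" shape along one deformation
mode over 120 frames, digitized twice with isotropic noise.  What these
synthetic data do *not* contain: real digitization biases (correlated
landmark drift, per-session scale error), so passing tests demonstrate
the machinery, not properties of real tooth germs; in particular the
published pooled-PCA variance figure depends on real landmarks and is
out of scope.

## Measurements and experiments

* **Growth angle**: angle at the knot's basal-node centroid between the
  vectors to the two cervical-loop tips (deepest non-fixed,
  non-knot basal epithelial node per bucco-lingual side, within a
  mid-frontal slab of two cell spacings in 3D); 180° = lateral bud
  walls, small = downward loops.  Because division events displace
  single nodes, growing-germ endpoints are reported as the mean over
  the last snapshots (`tail_mean_growth_angle`).
* **Loop depths**: per quadrant around the knot, depth of the deepest
  non-fixed basal node below the fixed border plane (3D).
* **Growth curves** (2D): suprabasal area by Delaunay triangulation
  over suprabasal + epithelial-basal nodes, keeping triangles whose
  edges are within 1.05 × the pairwise contact cut-off (the slack
  admits diagonal contacts of square/jittered packings); epithelial
  perimeter as the greedy nearest-neighbour path through the basal
  chain; both divided by a declared reference unit, so only unit-free
  comparisons are meaningful.  `curve_error` is the pooled RMSE over
  per-curve mean-normalized curves on the common percent-time grid —
  symmetric, nonnegative, zero iff identical.
* **Screens**: every grid combination runs with a per-row seed derived
  from the base seed and grid index, and reports germ measurements,
  the tail-mean angle and morphology flags.
* **Separation assay** (2D): the cap is first relaxed to equilibrium,
  then `b_EM` is set to zero and the system relaxed again with growth
  disabled (the ex-vivo deformation is much faster than growth).  The
  before/after angle follows the material tip cells of the intact cap
  (no growth occurs, so the anatomical curvature maxima are material
  loci; the geometric deepest-node rule would jump to drooping outer
  epithelium after detachment).  The reported width is the bounding
  width of the *follicular* mesenchyme (above the intact cap's
  knot-base depth), which recoils towards the mid line; the
  whole-mesenchyme bounding width is reported alongside and increases,
  because the released dental papilla decompresses.
* **Stress maps**: per-contact scalar `f_A` with tension positive and
  compression negative, plus per-epithelial-cell averages.
* **Geometric elongation model**: closed form; with tissue area growing
  as `e^{gt}`, the straight bucco-lingual loop fronts elongate as
  `e^{gt}` and the circular anterior/posterior fronts as `e^{gt/2}`, so
  the fitted exponent ratio is exactly 1/2.

## Morphometrics

Full Procrustes GPA (centring, unit centroid-size scaling,
rotation-only orthogonal fits iterated to a consensus with a 1e−12 mean
drift tolerance; reflections excluded because the landmarks are
anatomical).  Shape PCA on the aligned coordinates; variance fractions
sum to 1 and the consensus scores to zero.  The Procrustes ANOVA is a
Goodall-style decomposition into the main effect, among-unit residual
(frames within specimen) and within-unit digitizing error, with
`F = MS_effect/MS_error`, permutation P by seeded label permutation at
the unit level (999 by default; Procrustes data violate the classical
F assumptions, which is also reported), and a companion one-way ANOVA
on centroid size.  After the error check, replicates can be averaged
for downstream analyses.  TPS files round-trip coordinates and
specimen/frame/replicate labels.

## Reduced problem sizes

The in-silico experiments run at reduced scale: 2D germs of ~180–460
cells growing to ~350–1300, 3D germs of ~850–900 cells growing to
~1800–2100, horizons of 6–42 h chosen so each tissue expands a few
fold under the quoted rates.  Taking the printed per-hour rates over
the full two-day bud-to-cap span literally would imply astronomical
cell counts (e.g. 2²⁴-fold epithelial expansion), so horizons are set
by fold-change, not by the calendar span.

## Known limitations

* The suprabasal tension arch that should make the growth angle
  increase with suprabasal homotypic adhesion does not develop at the
  reduced 2D scale: stress maps show the confined suprabasal fill under
  net compression, so that screen trend is absent here (the
  mesenchymal-adhesion trend reproduces).
* After tissue separation the dominant response is the follicular
  mesenchyme recoil; the loop-angle increase is present but small,
  because part of the published opening is carried by the same missing
  suprabasal tension.
* No thermal noise, inertia, extracellular matrix, active migration,
  intercalation, contraction, or gene-network dynamics beyond the
  single knot signal; cells have no shape beyond 1–2 nodes.
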